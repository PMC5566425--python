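"""Shared fixtures: small motif models and a reduced-scale synthetic study."""

from __future__ import annotations

import numpy as np
import pytest

from erepipe.design import assign_strata, sample_subphase
from erepipe.motifs import build_model
from erepipe.simulate import SimulationConfig, emit_study, generate_study

#: 17-mer used throughout as a planted-motif payload (a published motif
#: instance from the chr16 validation records).
PLANT_17MER = "GTTGGTCTGGATGACTC"


@pytest.fixture(scope="session")
def acg_model():
    return build_model("ACG", pseudocount=0.1)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=11,
        region_length=60_000,
        n_variants=400,
        n_cohort=600,
        n_cases_sampled=80,
        n_controls_sampled=80,
        motif_plants=(
            ("AAGGTCACAGTGACCTA", 5_000, "+"),
            ("TTGGTCATCCTGACCGA", 20_000, "-"),
            ("CAGGTCAGTATGACCAC", 40_000, "+"),
        ),
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_study(small_config)


@pytest.fixture(scope="session")
def small_sample(small_bundle):
    p = small_bundle.phenotypes
    design = assign_strata(
        p["subject_id"], p["status"], p["g_a"], p["g_b"],
        index_snp_ids=small_bundle.truth.index_ids,
    )
    return sample_subphase(design, 80, 80, seed=5)


@pytest.fixture(scope="session")
def emitted_study(small_bundle, small_sample, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    return emit_study(small_bundle, small_sample, outdir)


def brute_force_scores(model):
    """Independent enumeration oracle: the exact score and probability of
    every one of the 4^width windows under the background model."""
    from itertools import product

    scores, probs = [], []
    for bases in product(range(4), repeat=model.width):
        scores.append(sum(model.log_odds[i, b] for i, b in enumerate(bases)))
        probs.append(float(np.prod([model.background[b] for b in bases])))
    return np.asarray(scores), np.asarray(probs)


def brute_force_tail(model, threshold, enumerated=None):
    """P(score >= threshold) by exhaustive enumeration."""
    scores, probs = enumerated if enumerated is not None else brute_force_scores(model)
    return float(probs[scores >= threshold].sum())


def gap_thresholds(scores, min_gap, k=5):
    """Midpoints of the k widest gaps between adjacent distinct scores.

    Thresholds this far from every attained score are immune to the
    DP's per-position rounding, so tail probabilities must match the
    enumeration exactly (to float precision).
    """
    uniq = np.unique(scores)
    gaps = np.diff(uniq)
    order = np.argsort(gaps)[::-1]
    mids = [
        (uniq[i] + uniq[i + 1]) / 2 for i in order[: 3 * k] if gaps[i] > min_gap
    ]
    return mids[:k]
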