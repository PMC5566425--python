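import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from erepipe.motifs import (
    build_model,
    default_ere_model,
    estimate_background,
    pvalue_of_score,
    read_bed,
    reverse_complement,
    scan_sequence,
    score_distribution,
    score_window,
    write_bed,
)

from conftest import PLANT_17MER, brute_force_scores, brute_force_tail, gap_thresholds


def assert_tail_sandwich(model, dist, threshold, enumerated):
    """DP tail at `threshold` bracketed by enumeration tails one bin away."""
    p = pvalue_of_score(dist, threshold)
    slop = (model.width / 2 + 1) * dist.granularity
    hi = brute_force_tail(model, threshold - slop, enumerated)
    lo = brute_force_tail(model, threshold + slop, enumerated)
    assert lo - 1e-12 <= p <= hi + 1e-12


class TestBuildModel:
    def test_17mer_consensus_width(self):
        model = build_model(PLANT_17MER)
        assert model.width == 17

    def test_single_base_zero_pseudocount_rejected(self):
        with pytest.raises(ValueError):
            build_model("A", pseudocount=0.0)

    def test_single_base_with_pseudocount(self):
        model = build_model("A", pseudocount=0.1)
        assert np.all(np.isfinite(model.log_odds))
        assert model.log_odds[0].argmax() == 0  # maximum at A

    def test_all_n_gives_zero_log_odds(self):
        model = build_model("NNN")
        assert np.allclose(model.log_odds, 0.0)

    def test_probability_rows_sum_to_one(self):
        model = build_model("ARNCT")
        assert np.allclose(model.probs.sum(axis=1), 1.0, atol=1e-9)

    def test_empty_consensus_rejected(self):
        with pytest.raises(ValueError):
            build_model("")

    def test_non_iupac_rejected(self):
        with pytest.raises(ValueError):
            build_model("ACGX")

    def test_matrix_spec_counts(self):
        counts = [[8, 0, 0, 0], [0, 8, 0, 0], [0, 0, 4, 4]]  # width x 4
        model = build_model(counts, pseudocount=0.1)
        assert model.width == 3
        assert model.probs[2, 2] == pytest.approx(0.5)

    def test_matrix_spec_transposed(self):
        counts = np.array([[8, 0, 0], [0, 8, 0], [0, 0, 4], [0, 0, 4]])  # 4 x width
        model = build_model(counts, pseudocount=0.1)
        assert model.width == 3

    def test_bad_background_rejected(self):
        with pytest.raises(ValueError):
            build_model("ACG", background=[0.5, 0.5, 0.0, 0.0])


class TestScoreWindow:
    def test_zero_information_model(self):
        model = build_model("NNN")
        assert score_window(model, "GAT") == pytest.approx(0.0)

    def test_hand_computed_consensus_score(self, acg_model):
        # independent arithmetic: per matched position the log-odds is
        # log2((1 + 0.1*0.25) / ((1 + 0.1) * 0.25))
        expected = 3 * math.log2((1 + 0.1 * 0.25) / (1.1 * 0.25))
        assert score_window(acg_model, "ACG") == pytest.approx(expected)

    def test_length_mismatch_rejected(self, acg_model):
        with pytest.raises(ValueError):
            score_window(acg_model, "ACGT")

    def test_n_scores_background_expectation(self, acg_model):
        expected = float(acg_model.background @ acg_model.log_odds[1])
        delta = score_window(acg_model, "ANG") - score_window(acg_model, "AAG")
        assert delta == pytest.approx(expected - acg_model.log_odds[1, 0])

    @given(st.text(alphabet="ACGT", min_size=5, max_size=5))
    @settings(max_examples=50, deadline=None)
    def test_strand_symmetry_identity(self, window):
        model = build_model("GGTCA", pseudocount=0.2)
        rc_model = model.reverse_complement()
        assert score_window(model, window) == pytest.approx(
            score_window(rc_model, reverse_complement(window))
        )


class TestScoreDistribution:
    def test_width_one_uniform(self):
        model = build_model("A", pseudocount=0.5)
        dist = score_distribution(model)
        # 4 column scores; C,G,T columns coincide -> bins merge
        assert dist.probs.sum() == pytest.approx(1.0, abs=1e-6)
        by_score = dist.pmf
        assert pytest.approx(0.25, abs=1e-12) == by_score[max(by_score)]

    def test_width3_matches_enumeration(self, acg_model):
        dist = score_distribution(acg_model)
        enumerated = brute_force_scores(acg_model)
        # exact equality at thresholds clear of any attained score
        min_gap = (acg_model.width + 2) * dist.granularity
        for t in gap_thresholds(enumerated[0], min_gap):
            assert pvalue_of_score(dist, t) == pytest.approx(
                brute_force_tail(acg_model, t, enumerated), abs=1e-9
            )
        # one-bin sandwich everywhere, including at attained scores
        for s in sorted(enumerated[0])[::7]:
            assert_tail_sandwich(acg_model, dist, s, enumerated)

    def test_width8_tail_matches_enumeration(self):
        rng = np.random.default_rng(42)
        counts = rng.integers(1, 20, size=(8, 4))
        model = build_model(counts, pseudocount=0.2)
        dist = score_distribution(model)
        enumerated = brute_force_scores(model)
        min_gap = (model.width + 2) * dist.granularity
        thresholds = gap_thresholds(enumerated[0], min_gap)
        assert len(thresholds) == 5
        for t in thresholds:
            assert pvalue_of_score(dist, t) == pytest.approx(
                brute_force_tail(model, t, enumerated), abs=1e-9
            )
        for t in rng.uniform(dist.support_min, dist.support_max, size=5):
            assert_tail_sandwich(model, dist, t, enumerated)

    def test_nonuniform_background(self):
        bg = [0.4, 0.1, 0.1, 0.4]
        model = build_model("ACG", background=bg, pseudocount=0.3)
        dist = score_distribution(model)
        enumerated = brute_force_scores(model)
        mid = (dist.support_min + dist.support_max) / 2
        assert_tail_sandwich(model, dist, mid, enumerated)

    def test_bad_granularity_rejected(self, acg_model):
        with pytest.raises(ValueError):
            score_distribution(acg_model, granularity=-1.0)


class TestPvalueOfScore:
    def test_support_min_gives_one(self, acg_model):
        dist = score_distribution(acg_model)
        assert pvalue_of_score(dist, dist.support_min) == 1.0
        assert pvalue_of_score(dist, dist.support_min - 5) == 1.0

    def test_above_support_max_gives_zero(self, acg_model):
        dist = score_distribution(acg_model)
        assert pvalue_of_score(dist, dist.support_max + 1e-6) == 0.0

    def test_monotone_non_increasing(self, acg_model):
        dist = score_distribution(acg_model)
        grid = np.linspace(dist.support_min - 1, dist.support_max + 1, 200)
        pvals = [pvalue_of_score(dist, s) for s in grid]
        assert all(a >= b for a, b in zip(pvals, pvals[1:]))


def _background_sequence(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


class TestScanSequence:
    def test_planted_forward_hit(self):
        rng = np.random.default_rng(1)
        seq = list(_background_sequence(rng, 2000))
        seq[100 : 100 + 17] = list(PLANT_17MER)
        model = build_model(PLANT_17MER)
        hits = scan_sequence("c", "".join(seq), model, alpha=1e-4)
        assert any(h.start == 100 and h.end == 117 and h.strand == "+" for h in hits)

    def test_planted_reverse_hit(self):
        rng = np.random.default_rng(1)
        seq = list(_background_sequence(rng, 2000))
        seq[400 : 400 + 17] = list(reverse_complement(PLANT_17MER))
        model = build_model(PLANT_17MER)
        hits = scan_sequence("c", "".join(seq), model, alpha=1e-4)
        match = [h for h in hits if h.start == 400 and h.end == 417 and h.strand == "-"]
        assert match and match[0].matched_seq == PLANT_17MER

    def test_empty_sequence(self):
        assert scan_sequence("c", "", build_model(PLANT_17MER)) == []

    def test_sequence_shorter_than_width(self):
        assert scan_sequence("c", "ACGT", build_model(PLANT_17MER)) == []

    def test_occurrence_width_equals_model_width(self):
        rng = np.random.default_rng(3)
        seq = _background_sequence(rng, 500)
        model = build_model("GGTCA", pseudocount=0.2)
        for h in scan_sequence("c", seq, model, alpha=0.05):
            assert h.end - h.start == model.width

    def test_alpha_monotonicity(self):
        rng = np.random.default_rng(4)
        seq = _background_sequence(rng, 1000)
        model = build_model("GGTCANNN", pseudocount=0.2)
        dist = score_distribution(model)
        loose = {
            (h.start, h.strand)
            for h in scan_sequence("c", seq, model, alpha=0.05, dist=dist)
        }
        tight = {
            (h.start, h.strand)
            for h in scan_sequence("c", seq, model, alpha=0.005, dist=dist)
        }
        assert tight <= loose

    def test_reverse_complement_scan_mirrors(self):
        rng = np.random.default_rng(5)
        seq = _background_sequence(rng, 800)
        model = build_model("GGTCAN", pseudocount=0.2)
        dist = score_distribution(model)
        fwd = scan_sequence("c", seq, model, alpha=0.02, dist=dist)
        rev = scan_sequence("c", reverse_complement(seq), model, alpha=0.02, dist=dist)
        L = len(seq)
        mirrored = {
            (L - h.end, L - h.start, "+" if h.strand == "-" else "-") for h in rev
        }
        assert {(h.start, h.end, h.strand) for h in fwd} == mirrored

    def test_n_windows_scored_not_skipped(self):
        model = build_model("NNNNN")
        hits = scan_sequence("c", "NNNNNNNNNN", model, alpha=1.0)
        assert len(hits) == 12  # 6 windows x 2 strands, all at p == 1

    def test_dedupe_keeps_better_pvalue(self):
        rng = np.random.default_rng(6)
        seq = _background_sequence(rng, 1500)
        model = build_model("GGTCANNNTGACC", pseudocount=0.2)
        dist = score_distribution(model)
        full = scan_sequence("c", seq, model, alpha=0.05, dist=dist)
        deduped = scan_sequence("c", seq, model, alpha=0.05, dist=dist, dedupe=True)
        assert len({(h.start, h.end) for h in full}) == len(deduped)

    def test_sorted_by_start_then_strand(self):
        rng = np.random.default_rng(7)
        seq = _background_sequence(rng, 1000)
        model = build_model("GGTC", pseudocount=0.2)
        hits = scan_sequence("c", seq, model, alpha=0.1)
        keys = [(h.start, h.strand) for h in hits]
        assert keys == sorted(keys)


class TestHelpers:
    def test_default_model_width_17(self):
        assert default_ere_model().width == 17

    def test_estimate_background_sums_to_one(self):
        bg = estimate_background("ACGGGGT")
        assert bg.sum() == pytest.approx(1.0)
        assert np.all(bg > 0)

    def test_estimate_background_floors_absent_base(self):
        bg = estimate_background("AAAA")
        assert bg[1] > 0  # C never seen but still positive

    def test_bed_round_trip(self, tmp_path):
        rng = np.random.default_rng(8)
        seq = _background_sequence(rng, 1000)
        model = build_model("GGTCAN", pseudocount=0.2)
        hits = scan_sequence("c", seq, model, alpha=0.05)
        path = tmp_path / "occ.bed"
        write_bed(hits, path)
        back = read_bed(path)
        assert [(h.start, h.end, h.strand) for h in back] == [
            (h.start, h.end, h.strand) for h in hits
        ]
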