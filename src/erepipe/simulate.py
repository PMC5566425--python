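"""Truth-tagged synthetic study generator.

Produces everything the analysis pipeline consumes — a reference
segment with planted motif instances, a full cohort of diploid
genotypes with a rare-skewed frequency spectrum and tunable LD
(including near-perfect planted pairs), case/control phenotypes driven
by planted log-odds effects, and two caller VCFs differing by injected
per-call discordance and missingness — together with a machine-readable
truth sidecar for oracle tests.

The haplotype model is deliberately simple: common variants within an
LD block are copied from a small pool of block haplotypes (inducing
local LD), rare variants are placed directly at their exact carrier
counts, and planted high-r pairs copy the partner's haplotype with a
configurable retention probability.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .design import CASE, CONTROL, SubphaseSample
from .io import write_fasta, write_phenotypes, write_vcf
from .motifs import reverse_complement
from .proximity import VariantSite
from .qc import MISSING, GenotypeMatrix

__all__ = [
    "CohortBundle",
    "SimulationConfig",
    "SyntheticTruth",
    "emit_study",
    "generate_cohort",
    "generate_reference",
    "generate_study",
]

BASES = "ACGT"

#: Default planted motif instances: strong matches to the padded
#: palindromic ERE consensus, placed well apart.
DEFAULT_MOTIF_PLANTS = (
    ("AAGGTCACAGTGACCTA", 50_000, "+"),
    ("TTGGTCATCCTGACCGA", 150_000, "-"),
    ("CAGGTCAGTATGACCAC", 300_000, "+"),
)

DEFAULT_PLANTED_EFFECTS = (("near_motif", 1.8), ("index_a", 1.5))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic study."""

    seed: int = 0
    contig: str = "region1"
    region_length: int = 500_000
    n_variants: int = 4_000
    spectrum: tuple[float, float, float] = (0.55, 0.04, 0.41)
    ld_block_length: int = 20_000
    pool_size: int = 16
    mutation_rate: float = 0.005
    planted_pairs: tuple[float, ...] = (0.99,)
    n_cohort: int = 1_763
    n_cases_sampled: int = 199
    n_controls_sampled: int = 201
    planted_effects: tuple[tuple[str, float], ...] = DEFAULT_PLANTED_EFFECTS
    motif_plants: tuple[tuple[str, int, str], ...] = DEFAULT_MOTIF_PLANTS
    caller_b_discordance: float = 2e-4  # per-call flip probability
    caller_b_missing: float = 0.02
    baseline_prevalence: float = 0.25
    index_freqs: tuple[float, float] = (0.35, 0.30)

    def __post_init__(self) -> None:
        if abs(sum(self.spectrum) - 1.0) > 1e-9:
            raise ValueError("spectrum fractions must sum to 1")
        for rate in (self.caller_b_discordance, self.caller_b_missing,
                     self.baseline_prevalence, self.mutation_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates and prevalence must lie in [0, 1]")
        for r in self.planted_pairs:
            if not 0 < r <= 1:
                raise ValueError("planted pair r targets must be in (0, 1]")
        seen: list[tuple[int, int]] = []
        for seq, offset, strand in self.motif_plants:
            if strand not in "+-":
                raise ValueError("plant strand must be '+' or '-'")
            if offset < 0 or offset + len(seq) > self.region_length:
                raise ValueError("motif plant outside the region")
            for s, e in seen:
                if offset < e and s < offset + len(seq):
                    raise ValueError("overlapping motif plants")
            seen.append((offset, offset + len(seq)))
        for role, odds in self.planted_effects:
            if role not in ("near_motif", "within_motif", "index_a", "index_b"):
                raise ValueError(f"unknown planted-effect role {role!r}")
            if odds <= 0:
                raise ValueError("odds ratios must be > 0")
        if self.n_variants < len(self.planted_effects) + 2 + len(self.planted_pairs):
            raise ValueError("n_variants too small for the planted structure")


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generator, for oracle tests."""

    true_maf: dict[str, float] = field(default_factory=dict)
    causal: list[dict] = field(default_factory=list)  # variant_id, beta, role
    motifs: list[dict] = field(default_factory=list)  # sequence, start, end, strand
    pairs: list[dict] = field(default_factory=list)   # id_a, id_b, r_target, realized_r
    index_ids: tuple[str, str] | None = None
    subject_strata: dict[str, str] = field(default_factory=dict)
    inclusion_prob: dict[str, float] = field(default_factory=dict)
    caller_b_flips: list[list[int]] = field(default_factory=list)
    caller_b_missing: list[list[int]] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["index_ids"] = list(self.index_ids) if self.index_ids else None
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("index_ids"):
            payload["index_ids"] = tuple(payload["index_ids"])
        return cls(**payload)


@dataclass
class CohortBundle:
    """Everything one simulated study comprises, in memory."""

    config: SimulationConfig
    reference: dict[str, str]
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    truth: SyntheticTruth


def _streams(config: SimulationConfig) -> list[np.random.Generator]:
    children = np.random.SeedSequence(config.seed).spawn(3)
    return [np.random.default_rng(c) for c in children]


def generate_reference(config: SimulationConfig) -> tuple[dict[str, str], list[dict]]:
    """I.i.d. background sequence with motif instances planted.

    Returns the FASTA record mapping and the motif truth list (0-based
    half-open intervals).  Byte-identical for identical configs.
    """
    rng = _streams(config)[0]
    seq = rng.choice(list(BASES), size=config.region_length)
    motifs = []
    for payload, offset, strand in config.motif_plants:
        inserted = payload if strand == "+" else reverse_complement(payload)
        seq[offset : offset + len(payload)] = list(inserted)
        motifs.append(
            {"sequence": payload, "start": offset,
             "end": offset + len(payload), "strand": strand}
        )
    return {config.contig: "".join(seq)}, motifs


def _special_positions(config: SimulationConfig) -> dict[str, int]:
    """1-based positions of index SNPs, pair partners and effect variants."""
    mid = config.region_length // 2
    positions: dict[str, int] = {
        "index_a": mid + 11,
        "index_b": min(mid + 50_011, config.region_length - 11),
    }
    for k in range(len(config.planted_pairs)):
        positions[f"pair_{k}"] = positions["index_a"] + 97 * (k + 1)
    plant_cycle = list(config.motif_plants)
    n_near = n_within = 0
    for i, (role, _) in enumerate(config.planted_effects):
        if role == "near_motif":
            seq, offset, _ = plant_cycle[n_near % len(plant_cycle)]
            positions[f"effect_{i}"] = offset + len(seq) + 101 + 37 * n_near
            n_near += 1
        elif role == "within_motif":
            seq, offset, _ = plant_cycle[(n_within + 1) % len(plant_cycle)]
            positions[f"effect_{i}"] = offset + 1 + (len(seq) // 2) + n_within
            n_within += 1
    if len(set(positions.values())) != len(positions):
        raise ValueError("planted structure produced colliding positions")
    return positions


def generate_cohort(
    config: SimulationConfig, reference: dict[str, str]
) -> tuple[GenotypeMatrix, pd.DataFrame, SyntheticTruth]:
    """Full-cohort genotypes, phenotypes and truth under the block model."""
    rng = _streams(config)[1]
    H = 2 * config.n_cohort
    seq = reference[config.contig]
    specials = _special_positions(config)

    # -- variant positions: random draw avoiding the reserved ones ----------
    n_random = config.n_variants - len(specials)
    forbidden = set(specials.values())
    draw = rng.choice(config.region_length, size=config.n_variants + len(specials) + 50,
                      replace=False) + 1
    random_pos = [int(p) for p in draw if p not in forbidden][:n_random]
    positions = sorted(random_pos + list(specials.values()))
    pos_rank = {p: i for i, p in enumerate(positions)}
    special_idx = {name: pos_rank[p] for name, p in specials.items()}

    # -- allele frequencies --------------------------------------------------
    M = config.n_variants
    bin_of = rng.choice(3, size=M, p=np.asarray(config.spectrum))
    freqs = np.empty(M)
    lo = 1.0 / H
    freqs[bin_of == 0] = rng.uniform(lo, 0.005, size=int((bin_of == 0).sum()))
    freqs[bin_of == 1] = rng.uniform(0.005, 0.01, size=int((bin_of == 1).sum()))
    freqs[bin_of == 2] = rng.uniform(0.01, 0.5, size=int((bin_of == 2).sum()))
    freqs[special_idx["index_a"]] = config.index_freqs[0]
    freqs[special_idx["index_b"]] = config.index_freqs[1]
    for k in range(len(config.planted_pairs)):
        freqs[special_idx[f"pair_{k}"]] = config.index_freqs[0]
    for i, (role, _) in enumerate(config.planted_effects):
        if f"effect_{i}" in special_idx:
            freqs[special_idx[f"effect_{i}"]] = 0.20

    # -- haplotypes ----------------------------------------------------------
    haps = np.zeros((H, M), dtype=np.int8)
    exact = np.zeros(M, dtype=bool)  # direct carrier placement
    exact[freqs <= 0.02] = True
    for name in special_idx:
        exact[special_idx[name]] = True
    pair_cols = {special_idx[f"pair_{k}"] for k in range(len(config.planted_pairs))}

    for j in np.nonzero(exact)[0]:
        if j in pair_cols:
            continue  # filled from the partner below
        c = max(1, int(round(freqs[j] * H)))
        carriers = rng.choice(H, size=min(c, H), replace=False)
        haps[carriers, j] = 1

    P = config.pool_size
    block_ids = np.asarray(positions) // config.ld_block_length
    for block in np.unique(block_ids):
        cols = np.nonzero((block_ids == block) & ~exact)[0]
        if cols.size == 0:
            continue
        pool = np.zeros((P, cols.size), dtype=np.int8)
        for jj, j in enumerate(cols):
            k = int(np.clip(round(freqs[j] * P), 1, P - 1))
            pool[rng.choice(P, size=k, replace=False), jj] = 1
        assignment = rng.integers(0, P, size=H)
        haps[:, cols] = pool[assignment]
        flips = rng.random((H, cols.size)) < config.mutation_rate
        sub = haps[:, cols]
        haps[:, cols] = np.where(flips, 1 - sub, sub)

    a_col = special_idx["index_a"]
    for k, r_target in enumerate(config.planted_pairs):
        j = special_idx[f"pair_{k}"]
        keep = rng.random(H) < r_target
        fresh = (rng.random(H) < freqs[j]).astype(np.int8)
        haps[:, j] = np.where(keep, haps[:, a_col], fresh)

    genotypes = (haps[0::2] + haps[1::2]).astype(np.int8)

    # -- variant records -----------------------------------------------------
    variants: list[VariantSite] = []
    for i, p in enumerate(positions):
        ref = seq[p - 1]
        alt = BASES[(BASES.index(ref) + 1 + int(rng.integers(0, 3))) % 4]
        variants.append(
            VariantSite(contig=config.contig, pos=p, ref_allele=ref,
                        alt_allele=alt, rsid=f"sv{i + 1:05d}")
        )
    matrix = GenotypeMatrix(
        subject_ids=[f"S{i + 1:04d}" for i in range(config.n_cohort)],
        variants=variants,
        calls=genotypes,
    )

    # -- phenotypes from planted log-odds ------------------------------------
    causal: list[dict] = []
    eta = np.zeros(config.n_cohort)
    for i, (role, odds) in enumerate(config.planted_effects):
        if role in ("index_a", "index_b"):
            j = special_idx[role]
        else:
            j = special_idx[f"effect_{i}"]
        beta = float(np.log(odds))
        g = genotypes[:, j].astype(float)
        eta += beta * (g - g.mean())  # center so prevalence stays on target
        causal.append({"variant_id": variants[j].variant_id,
                       "beta": beta, "role": role})
    prob = expit(logit(config.baseline_prevalence) + eta)
    is_case = rng.random(config.n_cohort) < prob
    phenotypes = pd.DataFrame(
        {
            "subject_id": matrix.subject_ids,
            "status": np.where(is_case, CASE, CONTROL),
            "g_a": genotypes[:, a_col].astype(int),
            "g_b": genotypes[:, special_idx["index_b"]].astype(int),
        }
    )

    # -- truth ---------------------------------------------------------------
    truth = SyntheticTruth(
        true_maf={
            v.variant_id: float(min(f, 1 - f))
            for v, f in zip(variants, genotypes.mean(axis=0) / 2.0)
        },
        causal=causal,
        index_ids=(
            variants[a_col].variant_id,
            variants[special_idx["index_b"]].variant_id,
        ),
    )
    for k, r_target in enumerate(config.planted_pairs):
        j = special_idx[f"pair_{k}"]
        ga = genotypes[:, a_col].astype(float)
        gj = genotypes[:, j].astype(float)
        realized = float(np.corrcoef(ga, gj)[0, 1])
        truth.pairs.append(
            {"id_a": variants[a_col].variant_id, "id_b": variants[j].variant_id,
             "r_target": float(r_target), "realized_r": realized}
        )
    return matrix, phenotypes, truth


def generate_study(config: SimulationConfig) -> CohortBundle:
    """Reference + cohort + truth in one call."""
    reference, motifs = generate_reference(config)
    matrix, phenotypes, truth = generate_cohort(config, reference)
    truth.motifs = motifs
    return CohortBundle(config=config, reference=reference, genotypes=matrix,
                        phenotypes=phenotypes, truth=truth)


def _inject_caller_b(
    calls: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, list[list[int]], list[list[int]]]:
    out = calls.copy()
    callable_mask = out != MISSING
    flip_mask = callable_mask & (rng.random(out.shape) < config.caller_b_discordance)
    # flip to one of the two other genotype values, uniformly
    shift = rng.integers(1, 3, size=out.shape)
    out[flip_mask] = (out[flip_mask] + shift[flip_mask]) % 3
    miss_mask = rng.random(out.shape) < config.caller_b_missing
    out[miss_mask] = MISSING
    flips = np.argwhere(flip_mask & ~miss_mask).tolist()
    missing = np.argwhere(miss_mask).tolist()
    return out, flips, missing


def emit_study(
    bundle: CohortBundle, sample: SubphaseSample, outdir
) -> dict[str, Path]:
    """Write the file bundle for a sampled study.

    Outputs: reference FASTA, caller-A VCF (true genotypes of the
    sampled subjects), caller-B VCF (with injected discordance and
    missingness), full-cohort phenotype TSV (stratum, weight, sampled
    flag) and the truth JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = bundle.config
    rng = _streams(config)[2]

    sampled_set = set(sample.subject_ids)
    rows = [i for i, sid in enumerate(bundle.genotypes.subject_ids) if sid in sampled_set]
    calls_a = GenotypeMatrix(
        subject_ids=[bundle.genotypes.subject_ids[i] for i in rows],
        variants=list(bundle.genotypes.variants),
        calls=bundle.genotypes.calls[rows, :].copy(),
    )
    calls_b_arr, flips, missing = _inject_caller_b(calls_a.calls, config, rng)
    calls_b = GenotypeMatrix(calls_a.subject_ids, list(calls_a.variants), calls_b_arr)

    truth = bundle.truth
    truth.caller_b_flips = flips
    truth.caller_b_missing = missing
    design = sample.design
    truth.subject_strata = {
        sid: "/".join(map(str, key)) for sid, key in design.subject_stratum.items()
    }
    truth.inclusion_prob = {}
    for s in design.strata:
        if s.n_cohort == 0:
            continue
        pi = s.n_sampled / s.n_cohort
        for sid, key in design.subject_stratum.items():
            if key == s.key:
                truth.inclusion_prob[sid] = pi

    pheno = bundle.phenotypes.copy()
    pheno["stratum"] = [
        "/".join(map(str, design.subject_stratum[sid]))
        if sid in design.subject_stratum else ""
        for sid in pheno["subject_id"]
    ]
    pheno["weight"] = [
        sample.weights.get(sid, np.nan) for sid in pheno["subject_id"]
    ]
    pheno["sampled"] = [int(sid in sampled_set) for sid in pheno["subject_id"]]

    paths = {
        "reference": outdir / "reference.fa",
        "caller_a": outdir / "caller_a.vcf",
        "caller_b": outdir / "caller_b.vcf",
        "phenotypes": outdir / "phenotypes.tsv",
        "truth": outdir / "truth.json",
    }
    contig_lengths = {config.contig: config.region_length}
    write_fasta(bundle.reference, paths["reference"])
    write_vcf(calls_a, paths["caller_a"], contig_lengths)
    write_vcf(calls_b, paths["caller_b"], contig_lengths)
    write_phenotypes(pheno, paths["phenotypes"])
    truth.to_json(paths["truth"])
    return paths
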