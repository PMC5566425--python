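"""Variant QC cascade for dual-workflow targeted resequencing calls.

Filters: cross-workflow discordance (any jointly called genotype that
disagrees), per-variant missingness (strictly > threshold), and
monomorphism.  Removal reasons follow the precedence
discordant > high-missing > monomorphic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .proximity import VariantSite

__all__ = [
    "GenotypeMatrix",
    "MISSING",
    "QCReport",
    "compute_maf",
    "concordance_filter",
    "concordance_rates",
    "merge_calls",
    "missingness_filter",
    "monomorphic_filter",
    "qc_pipeline",
]

logger = logging.getLogger(__name__)

MISSING = -1  # genotype code for a missing call


@dataclass
class GenotypeMatrix:
    """Diploid genotype calls: subjects x variants, codes {0,1,2,MISSING}."""

    subject_ids: list[str]
    variants: list[VariantSite]
    calls: np.ndarray  # int8, shape (n_subjects, n_variants)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.subject_ids), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.subject_ids)} subjects x {len(self.variants)} variants"
            )
        valid = np.isin(self.calls, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValueError("genotype codes must be in {0, 1, 2, missing}")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    def column(self, variant_id: str) -> np.ndarray:
        return self.calls[:, self.variant_ids.index(variant_id)]

    def missing_fraction(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=0)

    def subset_variants(self, keep: list[int]) -> "GenotypeMatrix":
        return GenotypeMatrix(
            subject_ids=list(self.subject_ids),
            variants=[self.variants[i] for i in keep],
            calls=self.calls[:, keep].copy(),
        )


def _check_aligned(a: GenotypeMatrix, b: GenotypeMatrix) -> None:
    if a.subject_ids != b.subject_ids or a.variant_ids != b.variant_ids:
        raise ValueError("matrices must share subjects and variants, in order")


def concordance_filter(a: GenotypeMatrix, b: GenotypeMatrix) -> set[str]:
    """Variant ids where any subject has differing non-missing calls.

    A call missing in exactly one workflow is not discordance; it only
    contributes to missingness downstream.
    """
    _check_aligned(a, b)
    both = (a.calls != MISSING) & (b.calls != MISSING)
    disagree = both & (a.calls != b.calls)
    flagged = disagree.any(axis=0)
    return {vid for vid, f in zip(a.variant_ids, flagged) if f}


def concordance_rates(a: GenotypeMatrix, b: GenotypeMatrix) -> dict[str, float]:
    """Per-variant agreement rate over jointly non-missing genotypes.

    Variants with no jointly called genotype get rate NaN.
    """
    _check_aligned(a, b)
    both = (a.calls != MISSING) & (b.calls != MISSING)
    agree = both & (a.calls == b.calls)
    n_joint = both.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        rates = np.where(n_joint > 0, agree.sum(axis=0) / n_joint, np.nan)
    return dict(zip(a.variant_ids, rates.tolist()))


def missingness_filter(calls: GenotypeMatrix, threshold: float = 0.10) -> set[str]:
    """Variants whose missing fraction is strictly greater than threshold."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    frac = calls.missing_fraction()
    return {vid for vid, f in zip(calls.variant_ids, frac) if f > threshold}


def monomorphic_filter(calls: GenotypeMatrix) -> set[str]:
    """Variants with at most one distinct non-missing genotype value.

    All-missing columns are vacuously monomorphic and are flagged (with
    a log message).
    """
    flagged = set()
    for j, vid in enumerate(calls.variant_ids):
        col = calls.calls[:, j]
        values = np.unique(col[col != MISSING])
        if len(values) <= 1:
            if len(values) == 0:
                logger.warning("variant %s has no non-missing calls", vid)
            flagged.add(vid)
    return flagged


def compute_maf(calls, weights=None) -> float:
    """Minor allele frequency from one variant's genotype codes.

    Unweighted: ``min(f, 1-f)`` with ``f = alt count / (2 * n called)``.
    With per-subject positive weights (inverse-probability weights from
    an outcome-dependent sampling design), allele counts are weighted,
    giving a design-consistent estimate of the source-cohort frequency.
    """
    g = np.asarray(calls, dtype=float)
    mask = g != MISSING
    if not mask.any():
        raise ValueError("all calls missing; MAF undefined")
    g = g[mask]
    if weights is None:
        f = g.sum() / (2.0 * g.size)
    else:
        w = np.asarray(weights, dtype=float)[mask]
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
        f = (w * g).sum() / (2.0 * w.sum())
    return float(min(f, 1.0 - f))


def merge_calls(a: GenotypeMatrix, b: GenotypeMatrix) -> GenotypeMatrix:
    """Merge two workflows: concordant value, else the single non-missing
    value, else missing.  Discordant calls become missing."""
    _check_aligned(a, b)
    merged = np.full_like(a.calls, MISSING)
    a_ok = a.calls != MISSING
    b_ok = b.calls != MISSING
    agree = a_ok & b_ok & (a.calls == b.calls)
    merged[agree] = a.calls[agree]
    only_a = a_ok & ~b_ok
    merged[only_a] = a.calls[only_a]
    only_b = b_ok & ~a_ok
    merged[only_b] = b.calls[only_b]
    return GenotypeMatrix(list(a.subject_ids), list(a.variants), merged)


@dataclass
class QCReport:
    """Counts and MAF spectrum from one run of the QC cascade."""

    n_input: int
    n_discordant: int
    n_high_missing: int
    n_monomorphic: int
    n_retained: int
    spectrum: dict[str, float] = field(default_factory=dict)
    removal_reasons: dict[str, str] = field(default_factory=dict)
    concordance_rates: dict[str, float] = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "n_input": self.n_input,
            "n_discordant": self.n_discordant,
            "n_high_missing": self.n_high_missing,
            "n_monomorphic": self.n_monomorphic,
            "n_retained": self.n_retained,
            "spectrum": self.spectrum,
            "removal_reasons": self.removal_reasons,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


# MAF bin edges for the spectrum summary: <=0.005, (0.005, 0.01], >0.01
SPECTRUM_EDGES = (0.005, 0.01)


def maf_spectrum(mafs) -> dict[str, float]:
    """Fractions of variants in the rare / less-common / common MAF bins."""
    m = np.asarray(mafs, dtype=float)
    if m.size == 0:
        return {"maf_le_0.005": 0.0, "maf_0.005_0.01": 0.0, "maf_gt_0.01": 0.0}
    lo, hi = SPECTRUM_EDGES
    return {
        "maf_le_0.005": float((m <= lo).mean()),
        "maf_0.005_0.01": float(((m > lo) & (m <= hi)).mean()),
        "maf_gt_0.01": float((m > hi).mean()),
    }


def qc_pipeline(
    calls_a: GenotypeMatrix,
    calls_b: GenotypeMatrix | None = None,
    threshold: float = 0.10,
) -> tuple[GenotypeMatrix, QCReport]:
    """Full QC cascade: concordance (if two call sets), missingness,
    monomorphism; returns the filtered matrix and a report.

    Missingness and monomorphism are evaluated on the merged calls when
    two workflows are supplied.  Each removed variant is attributed to a
    single primary reason with precedence
    discordant > high-missing > monomorphic.
    """
    if calls_b is not None:
        discordant = concordance_filter(calls_a, calls_b)
        rates = concordance_rates(calls_a, calls_b)
        merged = merge_calls(calls_a, calls_b)
    else:
        discordant, rates = set(), {}
        merged = calls_a
    high_missing = missingness_filter(merged, threshold)
    monomorphic = monomorphic_filter(merged)

    reasons: dict[str, str] = {}
    for vid in merged.variant_ids:
        if vid in discordant:
            reasons[vid] = "discordant"
        elif vid in high_missing:
            reasons[vid] = "high_missing"
        elif vid in monomorphic:
            reasons[vid] = "monomorphic"

    keep = [j for j, vid in enumerate(merged.variant_ids) if vid not in reasons]
    retained = merged.subset_variants(keep)
    mafs = [compute_maf(retained.calls[:, j]) for j in range(retained.n_variants)]
    counts = {"discordant": 0, "high_missing": 0, "monomorphic": 0}
    for r in reasons.values():
        counts[r] += 1
    report = QCReport(
        n_input=merged.n_variants,
        n_discordant=counts["discordant"],
        n_high_missing=counts["high_missing"],
        n_monomorphic=counts["monomorphic"],
        n_retained=retained.n_variants,
        spectrum=maf_spectrum(mafs),
        removal_reasons=reasons,
        concordance_rates=rates,
    )
    return retained, report
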