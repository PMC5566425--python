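"""Outcome-dependent two-phase stratified sampling and association models.

The sampling frame is stratified by case/control status crossed with
the joint genotypes of two index SNPs (2 x 3 x 3 = 18 strata when both
index SNPs show all three genotype classes).  A fixed number of cases
and controls is drawn by simple random sampling within strata, giving
each sampled subject an inverse-probability weight N/n for its stratum.

Two association models are provided per variant:

* ``weighted_marginal`` — logistic regression of case status on the
  additive genotype with the sampling weights and a robust (sandwich)
  variance, estimating the cohort-level marginal effect.
* ``adjusted_conditional`` — unweighted logistic regression adding the
  additive index-SNP genotype as a covariate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import statsmodels.api as sm

from .qc import MISSING, compute_maf

__all__ = [
    "AssociationResult",
    "CohortDesign",
    "Stratum",
    "SubphaseSample",
    "adjusted_association",
    "assign_strata",
    "ld_r",
    "proportional_allocation",
    "sample_subphase",
    "weighted_association",
]

logger = logging.getLogger(__name__)

CASE, CONTROL = "case", "control"


@dataclass(frozen=True)
class Stratum:
    case_status: str  # case | control
    g_a: int  # genotype at index SNP A (0/1/2)
    g_b: int  # genotype at index SNP B (0/1/2)
    n_cohort: int
    n_sampled: int = 0

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.case_status, self.g_a, self.g_b)

    @property
    def weight(self) -> float:
        if self.n_sampled == 0:
            raise ValueError(f"stratum {self.key} has no sampled subjects")
        return self.n_cohort / self.n_sampled


@dataclass
class CohortDesign:
    """Enumerated sampling strata plus the per-subject stratum map."""

    strata: list[Stratum]
    index_snp_ids: tuple[str, str]
    subject_ids: list[str]
    subject_stratum: dict[str, tuple[str, int, int]]
    excluded_subjects: list[str] = field(default_factory=list)

    def stratum(self, key: tuple[str, int, int]) -> Stratum:
        for s in self.strata:
            if s.key == key:
                return s
        raise KeyError(key)

    @property
    def n_strata(self) -> int:
        return len(self.strata)


def assign_strata(
    subject_ids,
    case_status,
    index_a,
    index_b,
    index_snp_ids: tuple[str, str] = ("index_a", "index_b"),
) -> CohortDesign:
    """Cross case/control status with joint index-SNP genotypes.

    Strata are enumerated as status x (observed genotype classes of
    SNP A) x (observed classes of SNP B); combinations absent from the
    cohort are retained with ``n_cohort = 0``.  Subjects with a missing
    index genotype are excluded from the frame and logged.
    """
    subject_ids = list(subject_ids)
    status = np.asarray(
        [s if s in (CASE, CONTROL) else (CASE if s else CONTROL) for s in case_status],
        dtype=object,
    )
    ga = np.asarray(index_a)
    gb = np.asarray(index_b)
    if not (len(subject_ids) == len(status) == len(ga) == len(gb)):
        raise ValueError("inputs must have one entry per subject")
    ok = (ga != MISSING) & (gb != MISSING)
    excluded = [sid for sid, o in zip(subject_ids, ok) if not o]
    if excluded:
        logger.warning("excluding %d subjects with missing index genotypes", len(excluded))
    ga_ok, gb_ok = ga[ok].astype(int), gb[ok].astype(int)
    for name, g in (("A", ga_ok), ("B", gb_ok)):
        if g.size and not np.isin(g, (0, 1, 2)).all():
            raise ValueError(f"index SNP {name} genotypes must be coded 0/1/2")
    classes_a = sorted(set(ga_ok.tolist())) or [0]
    classes_b = sorted(set(gb_ok.tolist())) or [0]

    kept = [sid for sid, o in zip(subject_ids, ok) if o]
    st_ok = status[ok]
    counts: dict[tuple[str, int, int], int] = {}
    subject_stratum: dict[str, tuple[str, int, int]] = {}
    for sid, st, a, b in zip(kept, st_ok, ga_ok, gb_ok):
        key = (str(st), int(a), int(b))
        counts[key] = counts.get(key, 0) + 1
        subject_stratum[sid] = key
    strata = [
        Stratum(st, a, b, counts.get((st, a, b), 0))
        for st in (CASE, CONTROL)
        for a in classes_a
        for b in classes_b
    ]
    return CohortDesign(
        strata=strata,
        index_snp_ids=tuple(index_snp_ids),
        subject_ids=kept,
        subject_stratum=subject_stratum,
        excluded_subjects=excluded,
    )


def proportional_allocation(
    design: CohortDesign, n_cases: int = 199, n_controls: int = 201
) -> dict[tuple[str, int, int], int]:
    """Per-stratum sample sizes proportional to N within each margin.

    Largest-remainder rounding, capped at stratum size, with overflow
    redistributed to strata with spare capacity.
    """
    alloc: dict[tuple[str, int, int], int] = {}
    for status, target in ((CASE, n_cases), (CONTROL, n_controls)):
        strata = [s for s in design.strata if s.case_status == status and s.n_cohort > 0]
        total = sum(s.n_cohort for s in strata)
        if target > total:
            raise ValueError(
                f"cannot sample {target} {status}s from a margin of {total}"
            )
        quotas = {s.key: target * s.n_cohort / total for s in strata}
        base = {k: min(math.floor(q), design.stratum(k).n_cohort) for k, q in quotas.items()}
        short = target - sum(base.values())
        # hand out remaining units by descending fractional remainder
        order = sorted(quotas, key=lambda k: quotas[k] - math.floor(quotas[k]), reverse=True)
        i = 0
        while short > 0:
            k = order[i % len(order)]
            if base[k] < design.stratum(k).n_cohort:
                base[k] += 1
                short -= 1
            i += 1
            if i > 10 * len(order) * (short + 1):  # pragma: no cover
                raise RuntimeError("allocation failed to converge")
        alloc.update(base)
    return alloc


@dataclass
class SubphaseSample:
    """A drawn subsample with per-subject inverse-probability weights."""

    subject_ids: list[str]
    weights: dict[str, float]
    design: CohortDesign  # copy with n_sampled filled in

    def weight_array(self, subject_ids=None) -> np.ndarray:
        ids = self.subject_ids if subject_ids is None else subject_ids
        return np.asarray([self.weights[s] for s in ids])


def sample_subphase(
    design: CohortDesign,
    n_cases: int = 199,
    n_controls: int = 201,
    allocation: dict | None = None,
    seed: int | None = None,
) -> SubphaseSample:
    """Simple random sampling without replacement within each stratum.

    ``allocation`` maps stratum keys to target sizes; by default it is
    proportional-to-N within the case and control margins.  Each sampled
    subject receives weight ``N_cohort / n_sampled`` of its stratum.
    Deterministic under ``seed``.
    """
    if allocation is None:
        allocation = proportional_allocation(design, n_cases, n_controls)
    for status, target in ((CASE, n_cases), (CONTROL, n_controls)):
        got = sum(n for k, n in allocation.items() if k[0] == status)
        if got != target:
            raise ValueError(f"{status} allocation sums to {got}, expected {target}")
    by_stratum: dict[tuple[str, int, int], list[str]] = {}
    for sid in design.subject_ids:
        by_stratum.setdefault(design.subject_stratum[sid], []).append(sid)
    rng = np.random.default_rng(seed)
    sampled: list[str] = []
    weights: dict[str, float] = {}
    new_strata = []
    for s in design.strata:
        n = int(allocation.get(s.key, 0))
        members = by_stratum.get(s.key, [])
        if n > len(members):
            raise ValueError(
                f"infeasible allocation: stratum {s.key} has {len(members)} "
                f"subjects, {n} requested"
            )
        new_strata.append(replace(s, n_sampled=n))
        if n == 0:
            continue
        chosen = [members[i] for i in rng.choice(len(members), size=n, replace=False)]
        w = s.n_cohort / n
        for sid in chosen:
            weights[sid] = w
        sampled.extend(chosen)
    order = {sid: i for i, sid in enumerate(design.subject_ids)}
    sampled.sort(key=order.__getitem__)
    new_design = CohortDesign(
        strata=new_strata,
        index_snp_ids=design.index_snp_ids,
        subject_ids=list(design.subject_ids),
        subject_stratum=dict(design.subject_stratum),
        excluded_subjects=list(design.excluded_subjects),
    )
    return SubphaseSample(subject_ids=sampled, weights=weights, design=new_design)


@dataclass(frozen=True)
class AssociationResult:
    variant_id: str
    model: str  # weighted_marginal | adjusted_conditional
    beta: float
    se: float
    p_value: float
    maf_sampled: float
    maf_weighted: float
    estimable: bool = True
    note: str = ""


def _non_estimable(variant_id: str, model: str, note: str, g, weights=None) -> AssociationResult:
    try:
        maf_s = compute_maf(g)
        maf_w = compute_maf(g, weights) if weights is not None else maf_s
    except ValueError:
        maf_s = maf_w = float("nan")
    return AssociationResult(
        variant_id, model, float("nan"), float("nan"), float("nan"),
        maf_s, maf_w, estimable=False, note=note,
    )


def _fit_logistic(y, X, weights=None):
    """GLM-binomial fit; robust (HC0 sandwich) covariance when weighted."""
    import warnings

    with warnings.catch_warnings():
        # near-separated fits emit benign overflow warnings before we
        # flag them non-estimable downstream
        warnings.simplefilter("ignore", RuntimeWarning)
        if weights is not None:
            fam = sm.families.Binomial()
            res = sm.GLM(y, X, family=fam, freq_weights=weights).fit(cov_type="HC0")
        else:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    return res


def _wald(res, idx: int) -> tuple[float, float, float]:
    beta = float(res.params[idx])
    se = float(res.bse[idx])
    from scipy import stats

    z = beta / se
    p = float(2 * stats.norm.sf(abs(z)))
    return beta, se, p


def _prepare(genotype, case_status):
    g = np.asarray(genotype, dtype=float)
    y = np.asarray(
        [1 if s in (1, True, CASE) else 0 for s in case_status], dtype=float
    )
    mask = g != MISSING
    return g, y, mask


def weighted_association(genotype, case_status, weights, variant_id="variant") -> AssociationResult:
    """Weighted marginal logistic model (IPW, sandwich variance)."""
    model = "weighted_marginal"
    g, y, mask = _prepare(genotype, case_status)
    w = np.asarray(weights, dtype=float)
    gm, ym, wm = g[mask], y[mask], w[mask]
    if gm.size == 0 or np.ptp(gm) == 0:
        return _non_estimable(variant_id, model, "genotype not polymorphic", g, w)
    if np.ptp(ym) == 0:
        return _non_estimable(variant_id, model, "outcome constant", g, w)
    X = sm.add_constant(gm)
    try:
        res = _fit_logistic(ym, X, weights=wm)
        beta, se, p = _wald(res, 1)
    except Exception as exc:  # separation / singular fits
        return _non_estimable(variant_id, model, f"fit failed: {exc}", g, w)
    if not (np.isfinite(beta) and np.isfinite(se) and se > 0):
        return _non_estimable(variant_id, model, "non-finite estimate", g, w)
    return AssociationResult(
        variant_id, model, beta, se, p,
        maf_sampled=compute_maf(g), maf_weighted=compute_maf(g, w),
    )


def adjusted_association(genotype, case_status, index_genotype, variant_id="variant") -> AssociationResult:
    """Unweighted logistic model adjusting for the index-SNP genotype.

    A constant adjustment covariate is dropped, reducing to the plain
    unadjusted fit.
    """
    model = "adjusted_conditional"
    g, y, mask = _prepare(genotype, case_status)
    gi = np.asarray(index_genotype, dtype=float)
    mask = mask & (gi != MISSING)
    gm, ym, gim = g[mask], y[mask], gi[mask]
    if gm.size == 0 or np.ptp(gm) == 0:
        return _non_estimable(variant_id, model, "genotype not polymorphic", g)
    if np.ptp(ym) == 0:
        return _non_estimable(variant_id, model, "outcome constant", g)
    cols = [np.ones_like(gm), gm]
    if np.ptp(gim) > 0:
        cols.append(gim)
    X = np.column_stack(cols)
    try:
        res = _fit_logistic(ym, X)
        beta, se, p = _wald(res, 1)
    except Exception as exc:
        return _non_estimable(variant_id, model, f"fit failed: {exc}", g)
    if not (np.isfinite(beta) and np.isfinite(se) and se > 0):
        return _non_estimable(variant_id, model, "non-finite estimate", g)
    return AssociationResult(
        variant_id, model, beta, se, p,
        maf_sampled=compute_maf(g), maf_weighted=compute_maf(g),
    )


def ld_r(calls_x, calls_y) -> float:
    """Pearson correlation of additive genotype codes (composite LD r).

    Computed over pairwise-complete subjects; raises on zero variance or
    fewer than two complete pairs.
    """
    x = np.asarray(calls_x, dtype=float)
    y = np.asarray(calls_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("genotype vectors must have equal length")
    mask = (x != MISSING) & (y != MISSING)
    if mask.sum() < 2:
        raise ValueError("need at least two pairwise-complete subjects")
    xm, ym = x[mask], y[mask]
    if np.ptp(xm) == 0 or np.ptp(ym) == 0:
        raise ValueError("zero genotype variance; r undefined")
    return float(np.corrcoef(xm, ym)[0, 1])
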