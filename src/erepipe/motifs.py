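"""Position-weight-matrix motif model with exact null score distributions.

Implements log-odds scoring of fixed-width sequence windows against a
0-order background, an exact (discretized) null distribution of window
scores computed by dynamic programming, and a both-strand occurrence
scan that reports hits below a p-value threshold — the classic
FIMO-style workflow for short regulatory motifs such as the estrogen
response element (ERE).

Coordinates of reported occurrences are 0-based half-open (BED-like).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MotifModel",
    "MotifOccurrence",
    "ScoreDistribution",
    "build_model",
    "default_ere_model",
    "estimate_background",
    "pvalue_of_score",
    "reverse_complement",
    "scan_sequence",
    "score_distribution",
    "score_window",
    "write_bed",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: IUPAC nucleotide codes mapped to the set of bases they stand for.
IUPAC_CODES: Mapping[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a sequence over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifModel:
    """A motif as per-position log-odds scores against a background.

    Attributes
    ----------
    width
        Motif width in bp.
    probs
        ``width x 4`` position probability matrix (columns A, C, G, T);
        each row sums to 1.
    log_odds
        ``width x 4`` matrix of log2 odds scores after pseudocount
        regularization.  All entries are finite when ``pseudocount > 0``.
    background
        Length-4 background base probabilities (A, C, G, T), all > 0.
    pseudocount
        Background-proportional pseudocount used in the log-odds
        transformation.
    source
        Free-text provenance (consensus string or matrix file name).
    """

    width: int
    probs: np.ndarray
    log_odds: np.ndarray
    background: np.ndarray
    pseudocount: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError("motif width must be >= 1")
        if self.probs.shape != (self.width, 4):
            raise ValueError("probability matrix must be width x 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each position's probabilities must sum to 1")
        if self.background.shape != (4,):
            raise ValueError("background must have 4 entries")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background probabilities must sum to 1")
        if np.any(self.background <= 0):
            raise ValueError("background probabilities must all be > 0")
        if not np.all(np.isfinite(self.log_odds)):
            raise ValueError(
                "log-odds matrix contains non-finite entries; use a "
                "positive pseudocount"
            )

    @property
    def expected_scores(self) -> np.ndarray:
        """Per-position background-expected score, used for N bases."""
        return self.log_odds @ self.background

    def reverse_complement(self) -> "MotifModel":
        """Model scoring the reverse-complement motif on the same background."""
        rc_probs = self.probs[::-1, ::-1].copy()
        rc_lo = self.log_odds[::-1, ::-1].copy()
        return MotifModel(
            width=self.width,
            probs=rc_probs,
            log_odds=rc_lo,
            background=self.background,
            pseudocount=self.pseudocount,
            source=f"revcomp({self.source})",
        )


@dataclass(frozen=True)
class MotifOccurrence:
    """A scored motif hit in 0-based half-open coordinates."""

    contig: str
    start: int
    end: int
    strand: str
    score: float
    pvalue: float
    matched_seq: str
    motif_id: str = "motif"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("occurrence end must exceed start")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


@dataclass(frozen=True)
class ScoreDistribution:
    """Discretized exact null distribution of window scores.

    ``keys`` are integer score bins (score ~= key * granularity) in
    increasing order; ``probs`` are the corresponding probabilities under
    i.i.d. background draws.  ``tail[i]`` is ``P(score >= keys[i])``.
    """

    granularity: float
    keys: np.ndarray
    probs: np.ndarray
    support_min: float
    support_max: float
    tail: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.granularity <= 0:
            raise ValueError("granularity must be > 0")
        if not np.isclose(self.probs.sum(), 1.0, atol=1e-6):
            raise ValueError("pmf must sum to 1")
        if self.tail is None:
            # reverse cumulative sum: tail[i] = sum(probs[i:])
            object.__setattr__(
                self, "tail", np.cumsum(self.probs[::-1])[::-1]
            )

    @property
    def pmf(self) -> dict[float, float]:
        """Mapping from (discretized) score to probability."""
        return {
            float(k * self.granularity): float(p)
            for k, p in zip(self.keys, self.probs)
        }


def _validate_background(background: Sequence[float] | None) -> np.ndarray:
    if background is None:
        bg = np.full(4, 0.25)
    else:
        bg = np.asarray(background, dtype=float)
    if bg.shape != (4,):
        raise ValueError("background must supply 4 probabilities (A,C,G,T)")
    if np.any(bg <= 0):
        raise ValueError("background probabilities must all be > 0")
    if not np.isclose(bg.sum(), 1.0, atol=1e-9):
        raise ValueError("background probabilities must sum to 1")
    return bg


def _probs_from_consensus(consensus: str) -> np.ndarray:
    probs = np.zeros((len(consensus), 4))
    for i, letter in enumerate(consensus.upper()):
        try:
            bases = IUPAC_CODES[letter]
        except KeyError:
            raise ValueError(
                f"non-IUPAC character {letter!r} at position {i}"
            ) from None
        for b in bases:
            probs[i, _BASE_INDEX[b]] = 1.0 / len(bases)
    return probs


def _probs_from_matrix(matrix) -> np.ndarray:
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2 or 4 not in arr.shape:
        raise ValueError("matrix must be 4 x width or width x 4")
    if arr.shape[0] == 4 and arr.shape[1] != 4:
        arr = arr.T  # rows were A,C,G,T
    if np.any(arr < 0):
        raise ValueError("matrix entries must be non-negative")
    totals = arr.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("every position needs a positive column total")
    return arr / totals[:, None]


def build_model(
    motif_spec,
    pseudocount: float = 0.1,
    background: Sequence[float] | None = None,
    source: str | None = None,
) -> MotifModel:
    """Build a :class:`MotifModel` from a consensus string or a matrix.

    Parameters
    ----------
    motif_spec
        Either a consensus string over IUPAC codes (degenerate letters
        expand to uniform probability over their base set) or a count /
        probability matrix with 4 rows or 4 columns in A,C,G,T order.
    pseudocount
        Non-negative background-proportional pseudocount ``c``.  The
        log-odds entry is ``log2((p + c*bg) / ((1 + c) * bg))``.
    background
        Background probabilities (A,C,G,T); uniform if omitted.

    Raises
    ------
    ValueError
        On an empty spec, a non-IUPAC character, or a zero probability
        entry combined with a zero pseudocount (which would produce a
        non-finite score).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    bg = _validate_background(background)
    if isinstance(motif_spec, str):
        if not motif_spec:
            raise ValueError("empty motif consensus")
        probs = _probs_from_consensus(motif_spec)
        src = source if source is not None else motif_spec
    else:
        probs = _probs_from_matrix(motif_spec)
        if probs.shape[0] == 0:
            raise ValueError("empty motif matrix")
        src = source if source is not None else "matrix"
    if pseudocount == 0 and np.any(probs == 0):
        raise ValueError(
            "zero probability entries with zero pseudocount would give "
            "non-finite log-odds scores; use pseudocount > 0"
        )
    with np.errstate(divide="ignore"):
        log_odds = np.log2((probs + pseudocount * bg) / ((1 + pseudocount) * bg))
    return MotifModel(
        width=probs.shape[0],
        probs=probs,
        log_odds=log_odds,
        background=bg,
        pseudocount=float(pseudocount),
        source=src,
    )


#: Palindromic ERE core consensus used for the shipped default model.
ERE_CORE_CONSENSUS = "GGTCANNNTGACC"


def default_ere_model(
    pseudocount: float = 0.1,
    background: Sequence[float] | None = None,
    width: int = 17,
) -> MotifModel:
    """Default ERE model: the palindromic core padded with N columns.

    The 13-bp core ``GGTCAnnnTGACC`` is centered and padded with
    uninformative N columns up to ``width`` (default 17).
    """
    pad = width - len(ERE_CORE_CONSENSUS)
    if pad < 0:
        raise ValueError("width must be >= core consensus length")
    left = pad // 2
    consensus = "N" * left + ERE_CORE_CONSENSUS + "N" * (pad - left)
    return build_model(consensus, pseudocount=pseudocount, background=background,
                       source=consensus)


def estimate_background(sequence: str, floor: float = 1e-3) -> np.ndarray:
    """0-order background composition of a sequence (N bases ignored).

    Frequencies are floored at ``floor`` and renormalized so that a
    base absent from the input still has positive background mass.
    """
    seq = sequence.upper()
    counts = np.array([seq.count(b) for b in BASES], dtype=float)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    freqs = np.maximum(counts / counts.sum(), floor)
    return freqs / freqs.sum()


def _encode(sequence: str) -> np.ndarray:
    """Map a sequence to codes 0..3 for A,C,G,T and 4 for N."""
    seq = sequence.upper()
    table = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
    table[ord("N")] = 4
    codes = table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if np.any(codes < 0):
        bad = seq[int(np.argmax(codes < 0))]
        raise ValueError(f"invalid sequence character {bad!r}")
    return codes


def _scoring_matrix(model: MotifModel) -> np.ndarray:
    """Log-odds matrix extended with a 5th column for N bases."""
    return np.column_stack([model.log_odds, model.expected_scores])


def score_window(model: MotifModel, window: str) -> float:
    """Log-odds score of a single window of exactly ``model.width`` bp.

    N bases contribute the position's background-expected score, so
    masked references remain scorable.
    """
    if len(window) != model.width:
        raise ValueError(
            f"window length {len(window)} != model width {model.width}"
        )
    codes = _encode(window)
    lo5 = _scoring_matrix(model)
    return float(lo5[np.arange(model.width), codes].sum())


def score_distribution(
    model: MotifModel, granularity: float | None = None
) -> ScoreDistribution:
    """Exact null pmf of the window score under i.i.d. background draws.

    Scores are discretized to integer multiples of ``granularity``
    (default: score range / 10,000) and convolved position by position.
    """
    span = float((model.log_odds.max(axis=1) - model.log_odds.min(axis=1)).sum())
    if granularity is None:
        granularity = max(span, 1e-9) / 10_000.0
    if granularity <= 0:
        raise ValueError("granularity must be > 0")

    # integer keys per position/base; DP convolution over positions
    keys = np.rint(model.log_odds / granularity).astype(np.int64)
    lo_total = int(keys.min(axis=1).sum())
    hi_total = int(keys.max(axis=1).sum())
    pmf = np.zeros(hi_total - lo_total + 1)
    offset = -lo_total
    pmf[offset] = 1.0  # score 0 before any position
    cur_lo = cur_hi = 0
    for i in range(model.width):
        nxt = np.zeros_like(pmf)
        for b in range(4):
            k = int(keys[i, b])
            p = model.background[b]
            if p == 0:
                continue
            src = pmf[cur_lo + offset : cur_hi + offset + 1]
            nxt[cur_lo + k + offset : cur_hi + k + offset + 1] += p * src
        pmf = nxt
        cur_lo += int(keys[i].min())
        cur_hi += int(keys[i].max())

    support = np.nonzero(pmf)[0]
    out_keys = support - offset
    out_probs = pmf[support]
    out_probs = out_probs / out_probs.sum()
    # true (un-discretized) extremes, both attained by some window
    return ScoreDistribution(
        granularity=float(granularity),
        keys=out_keys,
        probs=out_probs,
        support_min=float(model.log_odds.min(axis=1).sum()),
        support_max=float(model.log_odds.max(axis=1).sum()),
    )


def pvalue_of_score(dist: ScoreDistribution, score: float) -> float:
    """``P(null score >= score)`` under the discretized null pmf.

    Monotone non-increasing in ``score``; exact 1.0 at or below the
    support minimum and exact 0.0 above the support maximum.
    """
    return float(_pvalues_of_scores(dist, np.asarray([score]))[0])


def _pvalues_of_scores(dist: ScoreDistribution, scores: np.ndarray) -> np.ndarray:
    q = np.rint(scores / dist.granularity).astype(np.int64)
    # per-position rounding can push an attained score's key past the
    # DP's key range; clamp, then apply the exact support-bound guards
    q = np.clip(q, dist.keys[0], dist.keys[-1])
    idx = np.searchsorted(dist.keys, q, side="left")
    out = dist.tail[idx]
    out[scores <= dist.support_min] = 1.0
    out[scores > dist.support_max + 1e-9] = 0.0
    return out


def scan_sequence(
    contig_id: str,
    sequence: str,
    model: MotifModel,
    alpha: float = 1e-4,
    dist: ScoreDistribution | None = None,
    motif_id: str = "motif",
    dedupe: bool = False,
) -> list[MotifOccurrence]:
    """Scan both strands for windows with occurrence p-value <= alpha.

    Returns occurrences in 0-based half-open coordinates, sorted by
    (start, strand).  A '-' strand hit reports the reverse complement of
    the reference slice as its matched sequence.  Sequences shorter than
    the model width yield an empty list.  With ``dedupe=True``, only the
    better-p hit is kept when both strands fire on the same interval.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    seq = sequence.upper()
    L = len(seq)
    w = model.width
    if L < w:
        return []
    if dist is None:
        dist = score_distribution(model)

    codes = _encode(seq)
    lo5 = _scoring_matrix(model)
    rc5 = _scoring_matrix(model.reverse_complement())
    n_win = L - w + 1
    fwd = np.zeros(n_win)
    rev = np.zeros(n_win)
    for i in range(w):
        fwd += lo5[i, codes[i : i + n_win]]
        rev += rc5[i, codes[i : i + n_win]]
    hits: list[MotifOccurrence] = []
    for strand, scores in (("+", fwd), ("-", rev)):
        pvals = _pvalues_of_scores(dist, scores)
        for start in np.nonzero(pvals <= alpha)[0]:
            s = int(start)
            matched = seq[s : s + w]
            if strand == "-":
                matched = reverse_complement(matched)
            hits.append(
                MotifOccurrence(
                    contig=contig_id,
                    start=s,
                    end=s + w,
                    strand=strand,
                    score=float(scores[s]),
                    pvalue=float(pvals[s]),
                    matched_seq=matched,
                    motif_id=motif_id,
                )
            )
    if dedupe:
        best: dict[tuple[int, int], MotifOccurrence] = {}
        for occ in hits:
            key = (occ.start, occ.end)
            if key not in best or occ.pvalue < best[key].pvalue:
                best[key] = occ
        hits = list(best.values())
    hits.sort(key=lambda o: (o.start, o.strand))
    return hits


def write_bed(occurrences: Iterable[MotifOccurrence], path) -> None:
    """Write occurrences as BED6+2 (extra columns: p-value, matched seq)."""
    with open(path, "w") as fh:
        for occ in occurrences:
            fh.write(
                f"{occ.contig}\t{occ.start}\t{occ.end}\t{occ.motif_id}\t"
                f"{occ.score:.4f}\t{occ.strand}\t{occ.pvalue:.4g}\t"
                f"{occ.matched_seq}\n"
            )


def read_bed(path) -> list[MotifOccurrence]:
    """Read occurrences written by :func:`write_bed`."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(
                MotifOccurrence(
                    contig=f[0], start=int(f[1]), end=int(f[2]),
                    motif_id=f[3], score=float(f[4]), strand=f[5],
                    pvalue=float(f[6]) if len(f) > 6 else 1.0,
                    matched_seq=f[7] if len(f) > 7 else "",
                )
            )
    return out
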