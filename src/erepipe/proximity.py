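"""SNP-to-motif distance annotation and allele-level motif effect calls.

Distance convention: motif occurrences are 0-based half-open intervals,
SNP positions are 1-based (VCF-style), and the distance between a SNP
outside a motif and the motif is the number of reference bases strictly
between the SNP base and the nearest motif base.  A SNP inside the
motif's 1-based inclusive span has distance 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .motifs import MotifModel, MotifOccurrence, ScoreDistribution
from .motifs import pvalue_of_score, reverse_complement, score_distribution, score_window

__all__ = [
    "ProximityAnnotation",
    "VariantSite",
    "annotate_proximity",
    "annotations_to_frame",
    "classify_allele_effect",
    "snp_motif_distance",
]

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNV at a 1-based position."""

    contig: str
    pos: int
    ref_allele: str
    alt_allele: str
    rsid: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1 (1-based)")
        if self.ref_allele not in _VALID_BASES or self.alt_allele not in _VALID_BASES:
            raise ValueError("alleles must be single bases in {A,C,G,T}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")

    @property
    def variant_id(self) -> str:
        return self.rsid or f"{self.contig}:{self.pos}:{self.ref_allele}:{self.alt_allele}"


@dataclass(frozen=True)
class ProximityAnnotation:
    """Relation of one variant to one motif occurrence."""

    variant: VariantSite
    motif: MotifOccurrence
    relation: str  # within | near | far
    distance_bp: int
    allele_effect: str = "none"  # creates | disrupts | changes | none

    def __post_init__(self) -> None:
        if self.relation not in ("within", "near", "far"):
            raise ValueError(f"bad relation {self.relation!r}")
        if self.allele_effect not in ("creates", "disrupts", "changes", "none"):
            raise ValueError(f"bad allele_effect {self.allele_effect!r}")
        if (self.relation == "within") != (self.distance_bp == 0):
            raise ValueError("relation 'within' iff distance 0")


def snp_motif_distance(pos: int, motif_start: int, motif_end: int) -> int:
    """Distance in bp between a 1-based SNP and a 0-based half-open motif.

    0 when ``motif_start + 1 <= pos <= motif_end`` (the SNP base lies in
    the motif); otherwise the count of bases strictly between the SNP
    and the nearest motif base: ``motif_start - pos`` upstream,
    ``pos - motif_end - 1`` downstream.
    """
    if motif_start >= motif_end:
        raise ValueError("motif interval must satisfy start < end")
    if pos < 1:
        raise ValueError("pos must be >= 1")
    if motif_start + 1 <= pos <= motif_end:
        return 0
    if pos <= motif_start:
        return motif_start - pos
    return pos - motif_end - 1


def annotate_proximity(
    variants: Sequence[VariantSite],
    occurrences: Sequence[MotifOccurrence],
    window: int = 500,
) -> list[ProximityAnnotation]:
    """All (variant, motif) pairs on a shared contig within ``window`` bp.

    Every qualifying motif is reported per SNP, not only the nearest.
    The window is inclusive: distance == window is 'near', window + 1 is
    excluded.  Output is sorted by (variant pos, motif start, strand).
    """
    out: list[ProximityAnnotation] = []
    for v in variants:
        for occ in occurrences:
            if occ.contig != v.contig:
                continue
            d = snp_motif_distance(v.pos, occ.start, occ.end)
            if d == 0:
                out.append(ProximityAnnotation(v, occ, "within", 0))
            elif d <= window:
                out.append(ProximityAnnotation(v, occ, "near", d))
    out.sort(key=lambda a: (a.variant.pos, a.motif.start, a.motif.strand))
    return out


def _best_pvalue(
    sequence: str,
    var_index: int,
    allele: str,
    model: MotifModel,
    dist: ScoreDistribution,
) -> tuple[float, float]:
    """Best (smallest) p-value and its score over windows covering the variant.

    Both strands of every full-width window overlapping ``var_index``
    (0-based) are scored with ``allele`` substituted in.
    """
    w = model.width
    seq = sequence[:var_index] + allele + sequence[var_index + 1 :]
    best_p, best_score = 1.0, float("-inf")
    lo = max(0, var_index - w + 1)
    hi = min(len(seq) - w, var_index)
    for s in range(lo, hi + 1):
        window = seq[s : s + w]
        for candidate in (window, reverse_complement(window)):
            score = score_window(model, candidate)
            p = pvalue_of_score(dist, score)
            if p < best_p or (p == best_p and score > best_score):
                best_p, best_score = p, score
    return best_p, best_score


def classify_allele_effect(
    sequence: str,
    variant: VariantSite,
    model: MotifModel,
    alpha: float = 1e-4,
    tolerance_bits: float = 0.5,
    dist: ScoreDistribution | None = None,
) -> str:
    """Classify a SNP's effect on motif occurrence: creates / disrupts / changes / none.

    Scores every full-width window overlapping the variant position on
    both strands with the ref and the alt allele, takes the best
    p-value for each allele (``p_ref``, ``p_alt``) and applies::

        creates   p_alt <= alpha < p_ref
        disrupts  p_ref <= alpha < p_alt
        changes   both <= alpha and |score_alt - score_ref| > tolerance_bits
        none      otherwise

    ``variant.pos`` is interpreted as 1-based within ``sequence``.

    Raises
    ------
    ValueError
        If the reference base at the variant position does not equal
        ``variant.ref_allele``.
    """
    idx = variant.pos - 1
    if idx >= len(sequence):
        raise ValueError(
            f"variant position {variant.pos} beyond sequence of length {len(sequence)}"
        )
    observed = sequence[idx].upper()
    if observed != variant.ref_allele:
        raise ValueError(
            f"reference mismatch at position {variant.pos}: expected "
            f"{variant.ref_allele}, sequence has {observed}"
        )
    if dist is None:
        dist = score_distribution(model)
    p_ref, score_ref = _best_pvalue(sequence, idx, variant.ref_allele, model, dist)
    p_alt, score_alt = _best_pvalue(sequence, idx, variant.alt_allele, model, dist)
    if p_alt <= alpha < p_ref:
        return "creates"
    if p_ref <= alpha < p_alt:
        return "disrupts"
    if p_ref <= alpha and p_alt <= alpha and abs(score_alt - score_ref) > tolerance_bits:
        return "changes"
    return "none"


def annotate_vcf(in_vcf, out_vcf, annotations: Iterable[ProximityAnnotation]) -> None:
    """Copy a VCF, adding ERE_DIST / ERE_REL / ERE_EFF INFO fields.

    Each record gets the nearest qualifying motif's distance, relation
    and allele-effect call; unannotated records pass through untouched.
    Records are matched by rsid when present, else by contig:pos:ref:alt.
    """
    import pysam

    best: dict[str, ProximityAnnotation] = {}
    for a in annotations:
        vid = a.variant.variant_id
        if vid not in best or a.distance_bp < best[vid].distance_bp:
            best[vid] = a
    with pysam.VariantFile(str(in_vcf)) as vin:
        header = vin.header.copy()
        header.add_meta(
            "INFO", items=[("ID", "ERE_DIST"), ("Number", "1"), ("Type", "Integer"),
                           ("Description", "Distance in bp to the nearest ERE motif")],
        )
        header.add_meta(
            "INFO", items=[("ID", "ERE_REL"), ("Number", "1"), ("Type", "String"),
                           ("Description", "Relation to the nearest ERE motif")],
        )
        header.add_meta(
            "INFO", items=[("ID", "ERE_EFF"), ("Number", "1"), ("Type", "String"),
                           ("Description", "Allele-level motif effect call")],
        )
        with pysam.VariantFile(str(out_vcf), "w", header=header) as vout:
            for rec in vin:
                keys = [rec.id] if rec.id else []
                for alt in rec.alts or ():
                    keys.append(f"{rec.contig}:{rec.pos}:{rec.ref}:{alt}")
                hit = next((best[k] for k in keys if k in best), None)
                rec.translate(header)
                if hit is not None:
                    rec.info["ERE_DIST"] = hit.distance_bp
                    rec.info["ERE_REL"] = hit.relation
                    rec.info["ERE_EFF"] = hit.allele_effect
                vout.write(rec)


def annotations_to_frame(annotations: Iterable[ProximityAnnotation]) -> pd.DataFrame:
    """Tabular view of annotations, one row per (variant, motif) pair."""
    rows = [
        {
            "rsid": a.variant.variant_id,
            "contig": a.variant.contig,
            "pos": a.variant.pos,
            "motif_seq": a.motif.matched_seq,
            "motif_start": a.motif.start,
            "motif_end": a.motif.end,
            "strand": a.motif.strand,
            "distance_bp": a.distance_bp,
            "relation": a.relation,
            "allele_effect": a.allele_effect,
        }
        for a in annotations
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "rsid", "contig", "pos", "motif_seq", "motif_start", "motif_end",
            "strand", "distance_bp", "relation", "allele_effect",
        ],
    )
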