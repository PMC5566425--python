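"""End-to-end orchestration: scan -> QC -> proximity -> association -> report.

The report stage reproduces the candidate-table logic: SNPs within the
proximity window of a motif occurrence whose association p-value falls
below the threshold, one row per (SNP, motif) pair, sorted by ascending
p then genomic position, plus a distinct-motif count.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .design import (
    AssociationResult,
    adjusted_association,
    weighted_association,
)
from .motifs import (
    build_model,
    default_ere_model,
    estimate_background,
    scan_sequence,
    score_distribution,
    write_bed,
)
from .proximity import ProximityAnnotation, annotate_proximity, annotations_to_frame
from .qc import qc_pipeline

__all__ = [
    "CandidateRow",
    "build_candidate_table",
    "candidate_frame",
    "count_distinct_motifs",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

CANDIDATE_COLUMNS = [
    "rsid", "pos", "motif_seq", "motif_start", "motif_end", "strand",
    "distance_bp", "maf_sampled", "maf_weighted", "p_value",
]


@dataclass(frozen=True)
class CandidateRow:
    """One (SNP, motif) pair passing the distance and p-value filters."""

    rsid: str
    pos: int
    motif_seq: str
    motif_start: int
    motif_end: int
    strand: str
    distance_bp: int
    maf_sampled: float
    maf_weighted: float
    p_value: float

    def __post_init__(self) -> None:
        if self.motif_end <= self.motif_start:
            raise ValueError("motif end must exceed start")


def build_candidate_table(
    annotations: Sequence[ProximityAnnotation],
    associations: Mapping[str, AssociationResult],
    p_threshold: float = 1e-2,
    window: int = 500,
    include_within: bool = False,
) -> list[CandidateRow]:
    """Inner-join proximity annotations with association results.

    Emits one row per (SNP, qualifying motif) with ``distance <= window``
    and ``p < p_threshold``; 'within' SNPs (distance 0) are excluded
    unless ``include_within``.  Rows are sorted by ascending p, then SNP
    position, then motif start.
    """
    rows: list[CandidateRow] = []
    for ann in annotations:
        if ann.relation == "within" and not include_within:
            continue
        if ann.distance_bp > window:
            continue
        res = associations.get(ann.variant.variant_id)
        if res is None or not res.estimable:
            continue
        if not (res.p_value < p_threshold):
            continue
        rows.append(
            CandidateRow(
                rsid=ann.variant.variant_id,
                pos=ann.variant.pos,
                motif_seq=ann.motif.matched_seq,
                motif_start=ann.motif.start,
                motif_end=ann.motif.end,
                strand=ann.motif.strand,
                distance_bp=ann.distance_bp,
                maf_sampled=res.maf_sampled,
                maf_weighted=res.maf_weighted,
                p_value=res.p_value,
            )
        )
    rows.sort(key=lambda r: (r.p_value, r.pos, r.motif_start))
    return rows


def count_distinct_motifs(rows: Iterable[CandidateRow]) -> int:
    """Number of distinct (motif start, motif end, strand) triples."""
    return len({(r.motif_start, r.motif_end, r.strand) for r in rows})


def candidate_frame(rows: Sequence[CandidateRow]) -> pd.DataFrame:
    frame = pd.DataFrame([r.__dict__ for r in rows], columns=CANDIDATE_COLUMNS)
    return frame


def _format_candidates(frame: pd.DataFrame) -> pd.DataFrame:
    out = frame.copy()
    if len(out):
        out["p_value"] = [f"{p:.2E}" for p in out["p_value"]]
        out["maf_sampled"] = [f"{m:.5f}" for m in out["maf_sampled"]]
        out["maf_weighted"] = [f"{m:.6f}" for m in out["maf_weighted"]]
    return out


def _config_hash(config: dict) -> str:
    canon = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _write_tsv(frame: pd.DataFrame, path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.6g")


DEFAULTS = {
    "alpha": 1e-4,
    "window": 500,
    "p_threshold": 1e-2,
    "missing_threshold": 0.10,
    "assoc_model": "adjusted_conditional",
    "motif": None,           # consensus string; default palindromic ERE model
    "uniform_background": False,
    "include_within": False,
}


def run_pipeline(config: dict, outdir) -> dict[str, Path]:
    """Run scan -> QC -> proximity -> association -> candidate report.

    ``config`` must name the input files (``reference``, ``vcf``,
    optionally ``vcf_b``, ``phenotypes``) and may override any key in
    :data:`DEFAULTS`.  Outputs are deterministic given identical inputs
    and config; every table carries the config hash in a comment line.
    """
    cfg = {**DEFAULTS, **config}
    for key in ("reference", "vcf", "phenotypes"):
        if key not in cfg:
            raise ValueError(f"config is missing required input {key!r}")
        if not Path(cfg[key]).exists():
            raise FileNotFoundError(f"{key} file not found: {cfg[key]}")
    if cfg.get("vcf_b") and not Path(cfg["vcf_b"]).exists():
        raise FileNotFoundError(f"vcf_b file not found: {cfg['vcf_b']}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = _config_hash({k: str(v) for k, v in cfg.items()})

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("erepipe")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(cfg, outdir, chash)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(cfg: dict, outdir: Path, chash: str) -> dict[str, Path]:
    logger.info("pipeline start, config hash %s", chash)

    # motif scan
    reference = eio.read_fasta(cfg["reference"])
    all_seq = "".join(reference.values())
    background = None if cfg["uniform_background"] else estimate_background(all_seq)
    if cfg["motif"]:
        model = build_model(cfg["motif"], background=background)
    else:
        model = default_ere_model(background=background)
    dist = score_distribution(model)
    occurrences = []
    for contig, seq in reference.items():
        occurrences.extend(
            scan_sequence(contig, seq, model, alpha=cfg["alpha"], dist=dist)
        )
    logger.info("scan: %d occurrences at alpha %g", len(occurrences), cfg["alpha"])
    bed_path = outdir / "occurrences.bed"
    write_bed(occurrences, bed_path)

    # variant QC
    calls_a = eio.read_vcf(cfg["vcf"])
    calls_b = eio.read_vcf(cfg["vcf_b"]) if cfg.get("vcf_b") else None
    filtered, report = qc_pipeline(calls_a, calls_b, threshold=cfg["missing_threshold"])
    logger.info("qc: %d of %d variants retained", report.n_retained, report.n_input)
    qc_path = outdir / "qc_report.json"
    report.to_json(qc_path)

    # proximity
    annotations = annotate_proximity(filtered.variants, occurrences, window=cfg["window"])
    ann_frame = annotations_to_frame(annotations)
    ann_path = outdir / "annotations.tsv"
    _write_tsv(ann_frame, ann_path, chash)

    # association
    pheno = eio.read_phenotypes(cfg["phenotypes"])
    pheno = pheno.set_index("subject_id").loc[filtered.subject_ids]
    status = pheno["status"].tolist()
    index_g = pheno["g_a"].to_numpy()
    weights = pheno["weight"].to_numpy(dtype=float) if "weight" in pheno else np.ones(len(pheno))
    if np.any(~np.isfinite(weights)):
        raise ValueError("sampled subjects must all carry finite weights")
    assoc_rows = []
    associations: dict[str, AssociationResult] = {}
    for j, variant in enumerate(filtered.variants):
        g = filtered.calls[:, j]
        weighted = weighted_association(g, status, weights, variant.variant_id)
        adjusted = adjusted_association(g, status, index_g, variant.variant_id)
        for res in (weighted, adjusted):
            assoc_rows.append(
                {
                    "rsid": res.variant_id, "pos": variant.pos, "model": res.model,
                    "beta": res.beta, "se": res.se, "p": res.p_value,
                    "maf_sampled": res.maf_sampled, "maf_weighted": res.maf_weighted,
                    "estimable": int(res.estimable),
                }
            )
        chosen = weighted if cfg["assoc_model"] == "weighted_marginal" else adjusted
        associations[variant.variant_id] = chosen
    assoc_path = outdir / "associations.tsv"
    _write_tsv(pd.DataFrame(assoc_rows), assoc_path, chash)

    # candidate report
    rows = build_candidate_table(
        annotations, associations,
        p_threshold=cfg["p_threshold"], window=cfg["window"],
        include_within=cfg["include_within"],
    )
    cand_path = outdir / "candidates.tsv"
    _write_tsv(_format_candidates(candidate_frame(rows)), cand_path, chash)
    logger.info(
        "report: %d candidate rows over %d distinct motifs",
        len(rows), count_distinct_motifs(rows),
    )
    return {
        "occurrences": bed_path,
        "qc_report": qc_path,
        "annotations": ann_path,
        "associations": assoc_path,
        "candidates": cand_path,
        "log": outdir / "run.log",
    }
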