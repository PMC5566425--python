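"""File I/O: FASTA, VCF (GT-only) and phenotype TSV round-tripping."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .proximity import VariantSite
from .qc import MISSING, GenotypeMatrix

__all__ = [
    "read_fasta",
    "read_phenotypes",
    "read_vcf",
    "write_fasta",
    "write_phenotypes",
    "write_vcf",
]

_GT_FROM_CODE = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}


def read_fasta(path) -> dict[str, str]:
    """All records of a FASTA file as {id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()],
        str(path),
        "fasta",
    )


def write_vcf(matrix: GenotypeMatrix, path, contig_lengths: dict[str, int]) -> None:
    """Write a genotype matrix as an uncompressed VCF 4.2 with GT calls."""
    header = pysam.VariantHeader()
    for contig, length in contig_lengths.items():
        header.add_line(f"##contig=<ID={contig},length={length}>")
    header.add_meta(
        "FORMAT",
        items=[("ID", "GT"), ("Number", "1"), ("Type", "String"),
               ("Description", "Genotype")],
    )
    for sid in matrix.subject_ids:
        header.add_sample(sid)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for j, v in enumerate(matrix.variants):
            rec = vf.new_record(
                contig=v.contig,
                start=v.pos - 1,
                stop=v.pos,
                alleles=(v.ref_allele, v.alt_allele),
                id=v.rsid,
            )
            col = matrix.calls[:, j]
            for sid, code in zip(matrix.subject_ids, col):
                rec.samples[sid]["GT"] = _GT_FROM_CODE[int(code)]
            vf.write(rec)


def read_vcf(path) -> GenotypeMatrix:
    """Read GT calls from a VCF into a genotype matrix.

    Multi-allelic records are split into biallelic SNVs; non-SNV
    alleles are skipped.  A genotype carrying any other alt allele is
    treated as missing for the split-out variant.
    """
    variants: list[VariantSite] = []
    columns: list[np.ndarray] = []
    with pysam.VariantFile(str(path)) as vf:
        subject_ids = list(vf.header.samples)
        for rec in vf:
            ref = rec.ref.upper()
            if len(ref) != 1 or ref not in "ACGT":
                continue
            for alt_index, alt in enumerate(rec.alts or (), start=1):
                alt = alt.upper()
                if len(alt) != 1 or alt not in "ACGT" or alt == ref:
                    continue
                col = np.full(len(subject_ids), MISSING, dtype=np.int8)
                for i, sid in enumerate(subject_ids):
                    gt = rec.samples[sid].get("GT")
                    if gt is None or any(a is None for a in gt):
                        continue
                    if any(a not in (0, alt_index) for a in gt):
                        continue  # carries a different alt allele
                    col[i] = sum(1 for a in gt if a == alt_index)
                variants.append(
                    VariantSite(
                        contig=rec.contig, pos=rec.pos,
                        ref_allele=ref, alt_allele=alt, rsid=rec.id,
                    )
                )
                columns.append(col)
    calls = (
        np.column_stack(columns) if columns
        else np.zeros((len(subject_ids), 0), dtype=np.int8)
    )
    return GenotypeMatrix(subject_ids=subject_ids, variants=variants, calls=calls)


PHENOTYPE_COLUMNS = [
    "subject_id", "status", "g_a", "g_b", "stratum", "weight", "sampled",
]


def write_phenotypes(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_phenotypes(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "stratum": str})
    missing = set(PHENOTYPE_COLUMNS[:4]) - set(frame.columns)
    if missing:
        raise ValueError(f"phenotype table lacks columns: {sorted(missing)}")
    return frame
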