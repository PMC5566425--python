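"""Published ERE-proximal candidate SNP records for validation.

These are the printed candidate rows from a deep-resequencing study of
the ZNF423 (chromosome 16) and CTSO (chromosome 4) regions in a SERM
chemoprevention cohort: SNPs within +/- 500 bp of a scored ERE motif
occurrence whose breast-cancer association reached p < 1E-02.  Motif
coordinates are 0-based half-open; SNP positions are 1-based.

They pin down the coordinate and distance conventions of this package
(every printed distance must be reproduced exactly) and the
distinct-motif grouping logic, and serve as a realistic fixture for the
candidate-table report schema.
"""

from __future__ import annotations

from .pipeline import CandidateRow

__all__ = ["CHR16_CANDIDATES", "CHR4_CANDIDATES", "candidate_rows"]

# rsid, pos, motif sequence, motif start, motif end, strand, distance,
# MAF(400 subsample), MAF(cohort estimate), common variant, p-value
CHR16_RECORDS = [
    ("rs7187662", 49614038, "GTTGGTCTGGATGACTC", 49613770, 49613787, "-", 250, 0.20125, 0.219389, "T", 6.11e-04),
    ("rs72780324", 49691162, "CATGGATTCCCTGACCT", 49690861, 49690878, "+", 283, 0.05250, 0.049403, "A", 7.03e-04),
    ("rs746157", 49593393, "GAAGGGGCAGCTGACTC", 49592974, 49592991, "-", 401, 0.17250, 0.190402, "T", 8.44e-04),
    ("rs12925456", 49596645, "GATGGTCTTGATCTCCT", 49596906, 49596923, "+", 261, 0.17125, 0.189488, "T", 1.17e-03),
    ("rs11642983", 49597423, "GATGGTCTTGATCTCCT", 49596906, 49596923, "+", 499, 0.17125, 0.189488, "T", 1.17e-03),
    ("rs72780328", 49708387, "CAGAGCCACCCTGTCCT", 49708366, 49708383, "-", 3, 0.03625, 0.035656, "C", 1.98e-03),
    ("rs71382759", 49600680, "GATGAGCTAGCTCACCC", 49601144, 49601161, "+", 464, 0.09375, 0.115006, "C", 3.04e-03),
    ("rs12918288", 49593188, "GAAGGGGCAGCTGACTC", 49592974, 49592991, "-", 196, 0.09625, 0.116332, "G", 3.43e-03),
    ("rs57148286", 49688324, "CAGGGACAGCATGAGCT", 49688371, 49688388, "-", 47, 0.05875, 0.063394, "G", 6.23e-03),
]

CHR4_RECORDS = [
    ("rs1490555", 157251916, "CTGTTTCAGCTTGACTT", 157251780, 157251797, "+", 118, 0.18125, 0.175165, "T", 3.83e-03),
    ("rs1490556", 157251977, "CTGTTTCAGCTTGACTT", 157251780, 157251797, "+", 179, 0.18125, 0.175165, "A", 3.83e-03),
    ("rs1873358", 157252132, "CTGTTTCAGCTTGACTT", 157251780, 157251797, "+", 334, 0.18125, 0.175165, "A", 3.83e-03),
    ("rs2879978", 157252282, "CTGTTTCAGCTTGACTT", 157251780, 157251797, "+", 484, 0.18125, 0.175165, "G", 3.83e-03),
    ("rs10010729", 157248748, "GAAGGGTAAGAGGAACT", 157248919, 157248936, "-", 171, 0.16875, 0.165087, "G", 5.09e-03),
    ("rs1490554", 157251896, "CTGTTTCAGCTTGACTT", 157251780, 157251797, "+", 98, 0.16875, 0.165087, "A", 5.09e-03),
    ("rs2101586", 157261188, "CTGGGTTTACATGACCT", 157261391, 157261408, "+", 203, 0.16875, 0.165087, "C", 5.09e-03),
    ("rs6536168", 157261438, "CTGGGTTTACATGACCT", 157261391, 157261408, "+", 29, 0.16875, 0.165087, "C", 5.09e-03),
    ("rs4691210", 156919006, "TTAGGGTAGAATGACTC", 156918505, 156918522, "+", 483, 0.02125, 0.034025, "T", 7.99e-03),
    ("rs4691214", 156923110, "CAAAGCCAGCTGGACTT", 156923087, 156923104, "+", 5, 0.02125, 0.034025, "A", 7.99e-03),
    ("rs4691216", 156923435, "CATGGTCTCGCTGACTT", 156923576, 156923593, "-", 141, 0.02125, 0.034025, "C", 7.99e-03),
    ("rs4234895", 156923944, "CATGGTCTCGCTGACTT", 156923576, 156923593, "-", 350, 0.02125, 0.034025, "T", 7.99e-03),
]


def candidate_rows(records) -> list[CandidateRow]:
    """Published records as :class:`CandidateRow` objects."""
    return [
        CandidateRow(
            rsid=r[0], pos=r[1], motif_seq=r[2], motif_start=r[3],
            motif_end=r[4], strand=r[5], distance_bp=r[6],
            maf_sampled=r[7], maf_weighted=r[8], p_value=r[10],
        )
        for r in records
    ]


CHR16_CANDIDATES = candidate_rows(CHR16_RECORDS)
CHR4_CANDIDATES = candidate_rows(CHR4_RECORDS)
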