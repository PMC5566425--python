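# erepipe

A tested, reusable pipeline linking deep-resequencing variants to
estrogen response element (ERE) motifs in targeted (~500 kb) regions:

* **Motif scanning** (`erepipe.motifs`) — position-weight-matrix
  log-odds scoring with exact p-values computed by a discretized
  dynamic program over the background model, and a both-strand
  FIMO-style occurrence scan.  The shipped default motif is the 13-bp
  palindromic ERE core `GGTCAnnnTGACC`, N-padded to width 17; any
  consensus string (IUPAC codes) or 4-row count matrix can be
  substituted.
* **Proximity annotation** (`erepipe.proximity`) — SNP-to-motif
  distances and within/near classification, plus allele-level motif
  effect calls (creates / disrupts / changes / none).  Motif
  occurrences are 0-based half-open (BED-like), SNP positions 1-based
  (VCF-like), and the distance between a SNP outside a motif and the
  motif is the number of bases strictly between them.
* **Variant QC** (`erepipe.qc`) — dual-caller concordance filter
  (100% agreement over jointly called genotypes), strict >10%
  missingness filter, monomorphism filter, minor-allele frequencies
  (optionally inverse-probability weighted) and MAF spectrum summaries.
* **Two-phase design** (`erepipe.design`) — outcome-dependent
  stratified sampling over case/control status x joint index-SNP
  genotypes (18 strata), inverse-probability weights, and per-variant
  association under two models: weighted marginal logistic regression
  with a sandwich variance, and unweighted logistic regression adjusted
  for the index-SNP genotype.
* **Synthetic cohort generator** (`erepipe.simulate`) — truth-tagged
  reference + cohort + dual-caller VCF bundles with a rare-skewed
  frequency spectrum, block LD, planted high-r pairs, planted motif
  instances and planted motif-proximal risk variants.
* **Pipeline & CLI** (`erepipe.pipeline`, `erepipe.cli`) — scan -> QC ->
  annotate -> associate -> candidate report (SNPs within +/-500 bp of a
  motif with association p < 1E-02, one row per SNP/motif pair, plus a
  distinct-motif count).

## CLI

```sh
# generate a synthetic study bundle
erepipe simulate --seed 1 --out bundle/

# individual stages
erepipe scan bundle/reference.fa --out occurrences.bed
erepipe qc bundle/caller_a.vcf --vcf-b bundle/caller_b.vcf --out qc.json
erepipe annotate bundle/caller_a.vcf occurrences.bed --out annotations.tsv
erepipe assoc bundle/caller_a.vcf bundle/phenotypes.tsv --out associations.tsv
erepipe report annotations.tsv associations.tsv --out candidates.tsv

# or everything at once from a YAML config
cat > pipe.yaml <<YAML
reference: bundle/reference.fa
vcf: bundle/caller_a.vcf
vcf_b: bundle/caller_b.vcf
phenotypes: bundle/phenotypes.tsv
YAML
erepipe run-all --config pipe.yaml --out out/
```

Key flags: `--alpha` (per-window occurrence p-value threshold, default
1e-4), `--window` (proximity window, default 500 bp, inclusive),
`--p-threshold` (candidate reporting, default 1e-2), `--log-level`.

## File formats

FASTA references (multi-record allowed); uncompressed VCF 4.2 with GT
calls (multi-allelic records are split; non-SNV alleles skipped);
tab-separated phenotype tables (`subject_id`, `status`, `g_a`, `g_b`,
optional `stratum` / `weight` / `sampled`); BED6+2 motif occurrences
(extra columns: occurrence p-value, matched sequence); TSV reports.

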