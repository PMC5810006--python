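# pairedmet

Downstream analysis for paired primary/metastasis tumor-normal exome data:

- **Somatic filtering** — germline-VAF / alt-read / coverage / VAF threshold
  rules, programmatic QC proxies for manual review (normal support,
  single-strand evidence), relaxed shared-position selection for candidate
  gene panels, Ti/Tv and substitution-spectrum summaries, and per-patient
  mutation-load comparisons (pooled-variance t test).
- **CNV track** — per-SNP log2 ratio of library-size-normalized
  tumor/germline coverage, median recentering, 10-SNP moving average, and
  threshold/run-length segment calls with per-locus annotation.
- **LOH model** — tumor major-allele frequencies at germline-het SNPs, a
  Beta-Normal mixture over MAF in [0.5, 1] whose beta-component weight is
  the LOH fraction (tumor fraction and allelic-dropout rate are mapped from
  the component means), an exact binomial SNP-phase concordance test
  between paired lesions (single-region and 50-SNP moving window), and an
  artifact-LOH (false-negative) fraction estimator.
- **Enrichment stats** — gene-family mutation-table summaries
  (metastasis-only / primary-only / shared), an exact two-sided Fisher test
  (probability ordering, integer arithmetic), VAF trajectories across
  sequential lesions, and family prevalence per compartment.
- **Synthetic data** — a seeded generator of paired germline/primary/
  metastasis cases with het SNPs, purity-diluted copy-neutral LOH blocks,
  amplification dropout, CNV coverage segments and compartment-specific
  somatic rates with optional family enrichment. Ground truth is retained
  for recovery tests.
- **Fixtures** — packaged transcriptions of the published AKAP mutation and
  CNV tables (9-row and 4-row mutation tables, per-patient amp/del calls
  at 7 loci).

## CLI

```sh
pairedmet simulate --seed 17 --n-snps 5000 --purity 0.9 --out case/
pairedmet filter --in variants.tsv --out kept.tsv --rejected rejected.tsv \
    --max-germline-vaf 0.01 --min-alt-reads 5 --min-coverage 30 --min-vaf 0.16
pairedmet cnv --tumor tumor.tsv --germline germ.tsv --out track.tsv \
    --segments segments.bed --loci-bed akap_loci.bed
pairedmet loh-fit --snps tumor.tsv --germline germ.tsv --seed 17 --report fit.json
pairedmet phase-test --a primary.tsv --b met.tsv --window 50 --bed loh_blocks.bed
pairedmet enrich --table cohort1_akap --out report.json
pairedmet report            # combined fixture-derived summary
pairedmet run --simulate --seed 5 --out run/   # full pipeline on a simulated case
pairedmet run --fixtures --out run/            # enrichment stage on fixtures only
```

Configuration is a flat `section.key: value` YAML mapping
(`pairedmet filter --config config.yaml ...`); CLI flags override config
keys. Exit codes: 0 success, 2 validation error, 3 stage failure. Reruns
with the same seed and config are byte-identical (timestamps live only in
the run manifest).

## File formats

- SNP tables: TSV `chrom pos ref_count alt_count sample_id` (1-based).
- Variant tables: VarScan-like TSV (see `pairedmet.io_formats.VARIANT_COLUMNS`)
  or paired two-sample VCF 4.x with AD allele depths.
- Regions: BED (0-based half-open). Fit/stage reports: JSON.
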