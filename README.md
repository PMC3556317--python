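# triohet

Expression-heterosis analysis for a two-parent + F1 hybrid trio measured by
RNA-seq. Starting from a gene-level count matrix (two biological replicates
per genotype per stage), the pipeline computes:

- **RPKM normalization**, transcript coverage and detection summaries
  (`triohet.expression`),
- **differential expression** between the hybrid and each parent, and
  between the parents, with a conditional negative-binomial exact test,
  Benjamini–Hochberg FDR and the DEG rule FDR ≤ 0.05 & |log2FC| ≥ 1;
  DEGs are partitioned into hybrid-vs-parent (DG_HP) and parent-vs-parent
  (DG_PP) sets with Venn region counts (`triohet.de`),
- **additive/dominance decomposition** per gene via the trio ANOVA
  `y = u + a·x_a + d·x_d + replicate + e` on log2(RPKM+1), and
  classification of the dominance ratio h_p into AHP / HPL / MPL / LPL /
  BLP patterns using 99.8% confidence intervals for [d]−[a] (or [d]+[a])
  (`triohet.dominance`),
- **phenotype heterosis**: mid-parent (MPH) and high-parent (HPH)
  percentages with composite-variance / Welch t-tests
  (`triohet.phenotype`),
- **term enrichment** (hypergeometric, user-supplied annotation;
  `triohet.enrichment`), **hierarchical clustering** of samples on
  correlation distance (`triohet.clustering`) and **QTL-interval overlap**
  of candidate genes (`triohet.qtl`).

A synthetic-data module (`triohet.simulate`) generates negative-binomial
trio counts with known additive/dominance effects, trait phenotypes with
known MPH/HPH, annotations, QTL intervals and truth tables, so the whole
pipeline is testable without external data.

## CLI

```bash
triohet simulate --output-dir fixtures --n-genes 2000 --seed 1
triohet de --counts fixtures/counts.tsv --samples fixtures/samples.tsv \
    --genes fixtures/genes.tsv --stage tillering --contrast R/F --out de.tsv
triohet classify --counts fixtures/counts.tsv --samples fixtures/samples.tsv \
    --genes fixtures/genes.tsv --stage tillering --out effects.tsv
triohet heterosis --traits fixtures/traits.tsv --out heterosis.tsv
triohet run --config pipeline.yaml     # full pipeline from a YAML config
```

Other subcommands: `normalize`, `partition`, `enrich`, `cluster`,
`qtl-overlap`. All inputs and outputs are tab-separated text with a header
row; genomic coordinates are 1-based inclusive. A pipeline config lists
file paths and thresholds (`fdr_max`, `min_abs_log2fc`, `ci_level`,
`variance_mode`, `clustering_metric`, `overlap_rule`, `seed`, …); see
`triohet.pipeline.PipelineConfig` for the schema.

## Notes

- The exact test re-implements the conditional NB ("edgeR-style") test
  self-contained: library sizes are equalized by total-count scaling to
  the geometric mean, gene-wise method-of-moments dispersions are shrunk
  toward a trimmed-mean common value, and the split of each gene's total
  between groups is evaluated under a beta-binomial null (binomial in the
  Poisson limit). It is statistically analogous to, not bit-compatible
  with, edgeR.
- With two replicates the per-gene residual df is 2, so 99.8% t-intervals
  are degenerate; the default `variance_mode="pooled"` moderates residual
  variances toward the across-gene median (per-gene mode is available).
- Class MPL (partial dominance) is reported for genes whose CI falls on
  the mid-parent side rather than silently dropping them.
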