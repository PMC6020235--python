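# acetyldiff

Integrative differential histone-acetylation analysis: H3K27ac ChIP-seq and
RNA-seq, from per-sample peak calls to enriched transcription-factor binding
motifs linked to differentially expressed TFs.

The package is built for two-group epigenomic case/control designs (the
motivating setting is placental tissue from fetal-growth-restricted vs.
healthy pregnancies, n = 5 vs. 4): it answers *which regulatory regions gain
or lose H3K27ac, which genes respond, and which transcription factors tie
the two together*.

## What it computes

1. **Consensus regions** — per-sample peak calls (BED) are stretched to at
   least 2 kb (symmetric about the midpoint), pooled, merged by outermost
   coordinates, and filtered to autosomal regions supported by ≥ 2 samples.
2. **Differential testing** — a negative-binomial Wald engine shared by the
   ChIP and RNA arms. Per feature *i*, sample *j*:

   K<sub>ij</sub> ~ NB(μ<sub>ij</sub>, α<sub>i</sub>),  Var = μ + αμ²,
   log μ<sub>ij</sub> = log s<sub>j</sub> + β₀ᵢ + β₁ᵢ·x<sub>j</sub>

   with x the case indicator, s<sub>j</sub> median-of-ratios size factors
   and α<sub>i</sub> a trend-moderated method-of-moments dispersion. β₁ is
   fit by iteratively reweighted least squares; the Wald statistic β₁/se is
   referred to N(0,1) and Benjamini–Hochberg adjusted. Regions with
   padj < 0.05 are called hyper-/hypoacetylated; genes up-/downregulated.
3. **Exploratory structure** — quantile normalization → log2(x+1) → row
   median centering; hierarchical clustering of samples; PCA of the top 500
   most variable regions; Manhattan-plot table; robust PCA outlier flagging.
4. **Annotation & integration** — genes are linked to differential regions
   when the region overlaps ± 20 kb around the TSS; direction concordance
   (Wilcoxon shift tests of RNA log2FC near hyper/hypo regions) and the
   hyper∩up / hypo∩down overlap gene lists.
5. **Motif enrichment** — log-odds PWM scanning (both strands, hit =
   best window ≥ 80 % of the motif's maximum score) of foreground vs.
   background FASTA, one-sided Fisher's exact test per motif with BH
   correction, and a join of enriched motifs to differentially expressed TF
   transcripts.

A synthetic-data module generates every input with known ground truth
(planted fold changes, coupled expression, planted motifs), so the whole
pipeline is testable without any external download.

## Worked example

Simulate a full study and run everything:

```bash
acetyldiff -q run-all --synthetic --seed 7 --outdir demo
```

prints (also written to `demo/results/summary.tsv`):

```
consensus_regions       3000
differential_regions    102
hyper_regions           53
hypo_regions            49
pca_variance_pc1        0.4749582091700831
flagged_outlier_samples 3
de_genes_up             186
de_genes_down           194
annotated_genes_hyper   232
annotated_genes_hypo    203
overlap_hyper_up        121
overlap_hypo_down       127
median_lfc_near_hyper   1.6087928437469603
median_lfc_near_hypo    -1.7659423119044235
enriched_motifs         5
linked_tfs              5
```

Reading: of 3000 consensus regions, 102 are called differentially
acetylated (53 hyper, 49 hypo — the simulation plants 45 + 45, so calls
include a small number of false positives controlled at FDR 5 %). Genes
near hyper regions have strongly positive RNA log2 fold changes (median
+1.61) and near hypo regions negative (−1.77) — the expected
acetylation–expression concordance. All 5 planted motifs are recovered as
enriched and all 5 map to upregulated TF transcripts. PC1 captures ~47 % of
variance and separates the groups.

The same stages are available as subcommands (`simulate`, `consensus`,
`count`, `diff-chip`, `diff-rna`, `explore`, `annotate`, `motifs`) and as a
library of sklearn-style estimators:

```python
from acetyldiff import NBWaldTest, load_count_matrix
cm = load_count_matrix("chip_counts.tsv", groups={"s1": "case", ...})
res = NBWaldTest(p_threshold=0.05).fit(cm).results_   # DataFrame with log2fc, p, padj, direction
```

## Layout

```
src/acetyldiff/
  regions.py     interval algebra, consensus construction, BED I/O
  quantify.py    count matrices: read counting, TSV I/O, validation
  differential.py  NB Wald engine (size factors, dispersions, IRLS, BH)
  explore.py     quantile normalization, clustering, PCA, Manhattan table
  annotate.py    TSS-window annotation, concordance, overlap lists
  motifs.py      MEME parsing, PWM scanning, Fisher enrichment, TF linkage
  simulate.py    synthetic study generator with ground truth
  pipeline.py    orchestration, summary, MANIFEST
  cli.py         click CLI over the above
docs/methods.md  model assumptions, parameter choices, limitations
```
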