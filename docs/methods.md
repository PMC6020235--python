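# Methods

This note documents the statistical models, the parameter choices that
matter, what the synthetic-data generator does and does not emulate, and the
numerical decisions taken where the design was genuinely open.

## Consensus-region construction

Per-sample peaks are half-open 0-based intervals (BED convention
throughout). The construction is: stretch each peak to at least
`min_len = 2000` bp, pool all samples, merge overlapping intervals by their
outermost coordinates, keep regions supported by at least `min_support = 2`
samples, keep autosomes only (name allowlist chr1..chr22, configurable).

Open choices and how they were fixed:

* **Stretch anchor.** Stretching is symmetric about the interval midpoint to
  exactly `min_len`; this is the least-biased anchor when nothing more is
  known about peak shape. If the symmetric window would cross a chromosome
  boundary it is shifted to fit, preserving length; it is truncated only
  when the chromosome itself is shorter than `min_len`.
* **Overlap semantics.** Two intervals merge iff they share ≥ 1 bp.
  Book-ended intervals (end == start) do not merge — half-open semantics
  stated explicitly for reproducibility. The same rule defines sample
  support.
* **Support basis.** Support is counted against the stretched per-sample
  peaks — the same objects that were pooled and merged — not the raw peaks,
  for internal consistency of the merged list. Stretching happens before
  pooling.

## Read counting

Reads are reduced to their 5′ positions; a read is counted for a region
when that position lies in [start, end). Consensus regions are disjoint, so
each read is counted at most once. No fragment extension is applied
(extension belongs to peak calling, upstream of this package), and input is
assumed duplicate-collapsed; a loader check warns when > 10 % of rows are
exact duplicates.

## The negative-binomial Wald engine

Both arms (region counts, gene counts) use the same engine.

* **Normalization.** Median-of-ratios size factors: s_j = median over
  features positive in every sample of count_ij / (geometric mean of the
  feature). Only the *ratios* between samples are identified; the overall
  scale is arbitrary. Features with zero counts in every sample are dropped
  before testing (logged).
* **Dispersion.** Per-feature method-of-moments on normalized counts with a
  pooled *within-group* variance (so planted/real group effects do not
  inflate dispersion): α_i = max((var_i − mean_i)/mean_i², 1e-8). A
  mean-dispersion trend α = a₀ + a₁/mean is fitted by least squares across
  features and the final estimate is the blend
  (1 − w)·α_i + w·trend(mean_i) with w = 0.5. The floor of 1e-8 handles
  constant features; at least 3 samples are required.
* **GLM fit.** Log-link NB GLM with design [1, case indicator] and
  log-size-factor offsets, fitted per feature by Fisher scoring (IRLS) with
  α fixed, vectorized across features (the 2×2 normal equations are solved
  in closed form). Convergence: max coefficient change < 1e-8, cap of 100
  iterations; coefficients walking past |β| = 30 (degenerate groups, e.g.
  one group all zeros) are flagged, reported with p = NA, and excluded from
  the BH denominator. Standard errors come from the expected Fisher
  information at the solution; the Wald z = β₁/se is referred to N(0,1),
  two-sided. No LFC shrinkage, no Cox–Reid adjustment, no outlier
  replacement, no independent filtering: the design goal is calibration and
  unbiased fold-change recovery, not line-for-line equality with any
  particular reference implementation.
* **Multiple testing.** Benjamini–Hochberg step-up with monotonicity
  enforcement; NAs propagate and do not count toward m.
* **Direction calls.** Default: padj < 0.05 (both arms), hyper/up when
  log2fc > 0, hypo/down when < 0; a `use_padj=False` switch thresholds raw
  p instead. Thresholding adjusted p is the default because the headline
  region counts in this kind of study are reported at adjusted p.

Two exactness caveats worth knowing (both shared by DESeq2-style engines,
and both covered by tests at the appropriate tolerance):

* Scaling one sample's counts by c scales its size factor by c only in
  ratio to the other samples, and the pooled GLM estimate is only
  *near*-invariant (within ~0.05 log2 units at n = 9): rescaling one member
  of a group does not commute with offset-weighted pooling.
* A large *uni-directional* differential fraction biases median-of-ratios
  normalization (composition effect) and with it every fold-change
  estimate; recovery checks therefore plant balanced up/down effects, as
  in the emulated study (hyper and hypo regions both present).

## Exploratory structure

The visualization matrix is quantile-normalized, then log2(x + 1) (the
pseudocount of one read keeps zeros finite), then row-median-centered, in
that order (the order follows the conventional description of such
pipelines; it is configurable). Quantile normalization assigns each
column's sorted values the row-wise means of the column-sorted matrix; ties
within a column receive the mean of the tied target values. With ties the
classical invariants (idempotence, identical column multisets) hold only
approximately — exactly on tie-free columns — which the tests state
explicitly.

Hierarchical clustering of samples uses average linkage on Euclidean
distances (defaults, configurable); PCA takes the `n_top = 500` most
variable rows, centers them, and decomposes by SVD. Outlier flagging is a
report-only rule: a sample is flagged when its PC1 or PC2 score is more
than `k_sd = 3` robust SDs (1.4826·MAD within its group) from the group
median. With groups of 4–5 samples the MAD is noisy and flags are common;
the rule operationalizes "extreme outlier in the PCA" but exclusion is
always the analyst's decision.

## Annotation and integration

A gene links to a region when the region overlaps [tss − w, tss + w] with
w = 20 000 bp; equivalently the TSS-to-nearest-region-base distance is
≤ w. Distance is 0 when the TSS falls inside the region. Strand is ignored
for distance and retained for reporting. Genes linked to both hyper and
hypo regions appear in both gene sets (conflicts logged). Concordance is
summarized by the median RNA log2FC of genes near hyper regions, near hypo
regions, and of all genes, with one-sided Wilcoxon rank-sum tests in the
expected directions. Overlap lists are plain set intersections
(near-hyper ∩ up, near-hypo ∩ down), sorted by gene id.

## Motif enrichment

PWMs are position probability matrices (rows sum to 1, width ≥ 4,
probabilities floored at 1e-4 before log-odds). Scanning scores every
offset on both strands with Σ log2(p_base/bg_base) (background uniform 0.25
by default; optionally estimated from the background set); a sequence is a
hit when its best window reaches `score_fraction = 0.8` of the PWM's
maximum attainable score. Windows containing N (masked bases) never score.
This thresholded best-site rule is deliberately simple — deterministic and
closed-form verifiable — rather than a reproduction of any specific
enrichment tool's scoring. Enrichment per motif is a one-sided Fisher's
exact test of the foreground/background hit table, BH-corrected across
motifs. The TF-linkage step joins motifs enriched in the hyper-region
foreground to transcripts called up (and hypo to down) through a
user-supplied motif-name → gene-id map.

## The synthetic study generator

The generator emulates the statistical structure the analysis assumes, at
a desk scale that keeps the full test suite fast:

* 5 case vs. 4 control samples; 5 chromosomes of 10 Mb; 3000 true regions
  (400–1200 bp wide — sub-2-kb so the stretch rule is always exercised),
  non-overlapping with ≥ 5 kb gaps so consensus regions map unambiguously
  to truth; 1.5 % hyper + 1.5 % hypo with planted |log2FC| = 2.
* Per-sample peaks: true regions minus independent dropouts (rate 0.2),
  edges jittered ± 200 bp.
* Counts: NB with Var = μ + αμ², α = 0.05, baseline means log-uniform in
  [20, 500], sample size factors log-uniform in [0.5, 2]; regions passed in
  that overlap no true region get a background mean from the low end of
  the base-mean range.
* Expression: 5000 genes with uniform TSS (≥ 1 kb from chromosome ends); a
  gene whose TSS is within 20 kb of a hyper (hypo) region receives
  +2 (−2) log2FC with probability 0.7 (same window rule as the annotator,
  so concordance is a testable property); 2 % background DE with random
  sign; additionally the planted motifs' TF genes (motif_i → gene_i) are
  upregulated so the motif/DE-TF linkage is recoverable end to end.
* Sequences: 10 PWMs (width 8–12, consensus probability 0.85), of which
  the first 5 are planted; 200 foreground + 200 background sequences of
  500 bp uniform ACGT, consensus inserted at rate 0.5 (fg) vs. 0.05 (bg);
  an option injects masked N runs.

Determinism: one SeedSequence per configuration, one spawned child per
stage; a fixed (config, seed) yields byte-identical files, and the
end-to-end pipeline output is byte-identical across repeat runs.

What the generator does **not** emulate: read-level data (FASTQ/BAM),
fragment-length and GC effects, copy-number structure, correlated
biological replicates, realistic gene/peak density or chromosome sizes,
motif positional bias, and sequence composition beyond uniform ACGT.
Passing tests therefore demonstrate the correctness and calibration of the
algorithms under the assumed NB/uniform model — not robustness to the full
messiness of real sequencing data.

## Problem sizes and tolerances in the tests

The suite checks calibration at 5000 features (null rejection fraction of
raw p < 0.05 within [0.03, 0.07]), fold-change recovery over 500 planted
features (mean within [1.8, 2.2]), detection at the default configuration
(sensitivity ≥ 0.8, empirical FDR ≤ 0.10 at padj < 0.05), exact-oracle
equivalence for interval merging/support, annotation links, BH and Fisher
p-values (tail sums to 1e-12), and planted-motif recovery in ≥ 9/10 seeded
runs. Stochastic tests are fixed-seeded; the full suite runs in about a
minute.
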