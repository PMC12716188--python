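# Methods

This note documents the models implemented in `tregseq`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical conventions that make results reproducible.

## Count model

All count data — single-cell and bulk — are modelled as negative binomial
with mean μ and dispersion α, variance μ + αμ². The simulators draw from
exactly this parameterization (as a gamma–Poisson mixture), and the bulk
DE engine estimates and tests under it, so parameter-recovery tests are
self-consistent: a planted α or log₂ effect is the quantity the estimator
targets.

## Synthetic single-cell data

`simulate_sc_dataset` emulates a cleaned cells × genes count matrix as it
leaves upstream quantification and cell calling; ambient RNA, doublets and
UMI chemistry are deliberately out of scope.

Structure and defaults:

- 5,000 cells × 2,000 genes in 12 clusters; two rare Treg clusters at
  4.1% and 3.0% of cells — the fractions of the FOXP3⁺ populations the
  analysis is designed to detect. Desk scale keeps a full pipeline run
  under ~10 s; the statistical structure (rare clusters, panel folds,
  dispersion) is what matters for validity, not the absolute cell count.
- Per-gene baselines: log-normal (σ = 0.5) around a mean of 0.5 counts
  per cell; dispersion α = 0.8 (typical droplet-data overdispersion).
- Each non-Treg cluster carries 40 exclusive signature genes at 6-fold
  elevation so clusters are separable; the Treg clusters are defined by
  their 10-gene marker panels (canonical Treg genes such as CTLA4,
  TNFRSF18, IL2RA, …) at 8-fold elevation plus FOXP3.
- FOXP3: baseline mean 0.02 (≈ 2% of cells expressing — rare outside the
  Treg clusters by construction, comfortably under the 10% calling
  threshold), elevated 75-fold in Treg clusters (≈ 60–65% expressing).
- Library size: per-cell log-normal size factors (σ = 0.3), so
  normalization is non-trivially exercised.
- Batch: 2 batches; per-gene per-batch log-normal offsets (σ = 0.2),
  a location-type effect that per-batch centering of principal
  components removes exactly.
- Mitochondrial/ribosomal genes: 5% of the universe, recognizable by
  the "MT-"/"RPL"/"RPS" name-prefix convention (how such genes are
  flagged in practice when no annotation is supplied), with 3× hotter
  baselines so the flagged-fraction filter sees realistic values.

What passing tests show — and do not show: recovery results demonstrate
the pipeline's correctness on data satisfying the NB location-shift
cluster model with location-type batch effects. Real data add ambient
contamination, doublets, continuous (non-cluster) variation and nonlinear
batch effects; performance there is not certified by these tests.

## Single-cell pipeline

Stage order: cell QC → gene QC → normalize → HVG → PCA → batch-center →
kNN graph → Leiden → FOXP3 calling → marker ranking.

- **QC.** All thresholds are inclusive on the "keep" side (a cell with
  exactly 200 detected genes is kept). The mitochondrial/ribosomal
  fraction is a joint fraction over both gene classes. An all-zero
  cell's flagged fraction is defined as 0 (it fails `min_genes` anyway).
  Cells are filtered before genes, each in one pass.
- **Normalization.** Each cell is scaled to a common target (default:
  the median of per-cell totals) and log1p-transformed; zeros stay zero.
- **HVG.** Variance/mean dispersion of the log-scale values, z-scored
  within 20 equal-frequency mean bins; the bin count shrinks on small
  gene universes so each bin keeps ≥ ~20 members. Ties break by gene
  index. Default: top 500 genes.
- **PCA.** Exact SVD of the gene-centered HVG submatrix; each
  component's sign is fixed by making its largest-magnitude loading
  positive, so embeddings are bit-reproducible. Rank-deficient inputs
  return the available components with a warning. Default: 30
  components.
- **Batch centering.** Per batch and component, subtract the batch mean
  and restore the global mean. This replaces heavier iterative
  batch-integration methods by design: it is exact for the
  location-shift effects the simulator produces, transparent, and
  deterministic. It will not correct batch effects that change
  covariance structure.
- **kNN graph.** k = 15 (the common default), Euclidean in the
  embedding, symmetrized (an edge exists if either endpoint selects the
  other); weights are a Gaussian kernel on distance scaled by the mean
  kNN distance, hence in (0, 1]. Distance ties break by cell index.
- **Leiden.** RBConfiguration objective (resolution-parameterized
  configuration-null modularity), resolution 1.5 by default, seeded;
  labels are relabelled by decreasing cluster size (ties by original
  label). The single pipeline seed drives clustering.

## FOXP3 calling and marker statistics

- **Wilcoxon one-vs-rest.** Exact permutation enumeration of the
  rank-sum distribution (midranks, so ties are exact) when both groups
  have ≤ 8 observations; otherwise the tie-corrected normal
  approximation without continuity correction — with midranks the
  rank-sum lattice is not unit-spaced, and permutation-oracle checks
  show the uncorrected z is the more accurate choice on tied data. All
  values tied gives p = 1.
- **FOXP3 clusters.** A cluster is called when the one-vs-rest test on
  FOXP3 is significant (default p ≤ 0.05) in the positive direction and
  FOXP3 is expressed (raw count > 0) in ≥ 10% of its cells. The
  percent-expressing condition blocks calls driven by a few extreme
  cells.
- **Ratio score.** Clusters are ordered by mean log-normalized
  expression of the gene; the designated cluster must be the *strict*
  unique maximum, otherwise the score is 0 (the conservative reading of
  a tie at the top). If the second-highest mean is 0, the denominator
  falls back to the smallest positive mean in the table and the score is
  flagged `infinite_like`; this preserves downstream ranking without
  special cases.
- **Layers.** Means come from the normalized log layer;
  percent-expressing from raw counts (> 0). Both are kept explicit in
  the output tables.
- **Marker ranking.** Candidates need BH-adjusted Wilcoxon p ≤ 0.05
  (adjustment across genes within the cluster) and a positive ratio
  score; they are ordered by decreasing score, ties by gene id. The
  log₂ fold change uses the rank-genes convention
  `log2((expm1(mean_in)+ε)/(expm1(mean_rest)+ε))`, ε = 1e-9.

## Bulk differential expression

Design: treatment coding with CD25 reference level "negative" and the
alphabetically first sex as reference; full model `~ sex + CD25`, reduced
`~ sex`. Default contrasts: high-vs-negative, low-vs-negative,
high-vs-low.

- **Size factors.** Median-of-ratios: s_j = median over reference genes
  (strictly positive in every sample) of count/geometric mean. Absence
  of reference genes is an error, not a silent fallback.
- **Dispersion.** Per-gene method of moments on normalized counts with
  design-fitted means: α̂ = (s²_resid − q̄·mean(1/s))/q̄², floored at
  1e-8. Raw per-gene moment estimates at 12 samples are far too noisy to
  calibrate tests (their sampling error inflates Wald type-I error to
  ≈ 0.09 at nominal 0.05), so the fitted pipeline shrinks them toward a
  Cox–Reid adjusted common dispersion — the one-parameter analogue of
  the moderation every established bulk DE engine performs — with prior
  weight 40 degrees of freedom against the residual df. The CR term
  corrects the downward bias from profiling out p coefficients per gene.
  With shrinkage, null simulations at the study design give type-I error
  ≈ 0.05 and uniform LRT p-values. The raw estimator remains available
  (`moderate=False`) and is the right tool when genes genuinely differ
  wildly in dispersion and samples are many.
- **GLM.** IRLS with log link and offset log s_j; convergence when
  max |Δβ| < 1e-8, flag set after 100 iterations. Standard errors from
  the inverse Fisher information at the final weights. All-zero genes
  are skipped and reported as NA.
- **Wald / LRT.** Wald: two-sided normal on c′β̂/SE. LRT: 2Δℓ against χ²
  with df = rank difference (2 for the CD25 factor); full and reduced
  fits share the gene's dispersion. Identical designs give stat 0,
  p = 1.
- **Multiple testing.** BH within each contrast; NA p-values propagate
  and are excluded from the denominator. No LFC shrinkage and no
  independent filtering; `base_mean` is reported so users can filter.
- **Z-scores.** Per gene across the three condition means of normalized
  counts, sample SD (ddof = 1); constant genes map to zeros.
- **Venn.** Significant genes (padj ≤ cutoff, by direction) partitioned
  into the 7 regions of the three pairwise contrasts.

## Synthetic bulk data

12 samples (3 CD25 groups × 4, sexes balanced 2/2 within group), per-gene
baselines log-uniform on [20, 2000], dispersion α = 0.1, per-sample
log-normal size factors (σ = 0.3), planted per-gene log₂ effects for the
low/high groups and sex. Note that planting the *same* effect in every
gene is indistinguishable from a library-size shift and is absorbed by
normalization — recovery experiments plant effects in a subset (e.g. 10%)
of genes, balanced in sign where the point is effect-size recovery.

## qPCR

ΔCT = CT_target − CT_reference per sample; ΔΔCT subtracts the arithmetic
mean ΔCT of the control group (equivalently, the geometric mean on the
linear scale), so the control aggregate's fold is exactly 1; fold =
2^(−ΔΔCT). Fold changes are summarized as mean ± SD per group, and group
comparisons (one-way ANOVA + Tukey HSD, with the usual star annotations)
run on the fold-change scale to match how such panels are reported; the
analysis scale is a flag. The simulator draws reference CTs around 20
and target CTs as reference + group ΔCT + Gaussian noise; it does not
model primer efficiency or standard curves.

## Determinism

Every generator and every pipeline stage is deterministic given its seed:
a single run seed drives simulation, clustering and all derived outputs,
and repeated runs with the same inputs produce byte-identical tables
(timestamps live only in the run log). Exact SVD, fixed sign conventions,
stated tie-breaks and seeded Leiden are what make this hold.

## Known limitations

- Batch correction is location-only (see above).
- Dispersion moderation assumes dispersions are exchangeable around a
  common centre; a mean–dispersion trend is not fitted.
- The Wilcoxon large-sample branch is an approximation; it is accurate
  to well under 2% relative error against permutation oracles at the
  group sizes the pipeline encounters, but exact enumeration is only
  used for tiny groups.
- The qPCR module assumes 100% amplification efficiency (the textbook
  2^(−ΔΔCT) model).
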