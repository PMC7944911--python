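# Methods

## Model and assumptions

`gliosom` treats each subject as six co-registered scalar volumes
(CE-T1WI, T2WI, FLAIR, ADC, rCBV, FDOPA-SUV) on one voxel grid, with a
binary whole-brain mask and a binary tumor ROI (the FLAIR-hyperintense
region) supplied as inputs.  Registration, segmentation, and the
computation of derived maps (ADC, rCBV, SUV) are upstream of this package
and assumed done.  The pipeline's premise is that the joint 6-D intensity
distribution of brain voxels decomposes into a modest number of tissue
signatures, and that the *composition* of a tumor in those signatures is
informative about IDH genotype.

## Normalization

Channel intensities are heavy-tailed (contrast enhancement, hot PET foci),
so each channel is rescaled per subject by the robust upper bound
`u = P75 + 1.5·IQR` computed over brain-mask voxels, with percentiles by
linear interpolation between order statistics.  Division by `u` maps
`[0, u]` onto `[0, 1]`; values above `u` (and any negative values) are kept
as-is — there is deliberately no clipping, so outliers survive into the
feature space.  Percentiles are computed over the brain mask only, because
background zeros would otherwise dominate the order statistics.  An
all-zero channel makes `u ≤ 0` and is rejected with the channel named.

## Two-level clustering

Training voxels are taken on a deterministic stride-4 lattice anchored at
index (0,0,0) — one voxel per 4×4×4 block — restricted to the brain mask,
and column-stacked across the cohort.  Tumor voxels are *not* excluded:
the protoclusters must cover tumor tissue to label it later.

The first level is a rectangular batch SOM (default 20×20 = 400 nodes,
50 epochs).  Weights are initialized on the plane of the first two
principal components (linear initialization); each epoch assigns all
vectors to best-matching units (BMUs) and replaces every weight with the
Gaussian-neighborhood-weighted mean of the data, the radius decaying
linearly from half the grid diagonal to 1.  Batch training with linear
initialization is fully deterministic, which makes cohort-level runs
bit-reproducible.  BMU ties break toward the lowest row-major node index.

The second level is K-means (k-means++, Lloyd, best of 10 restarts by
within-cluster sum of squares) over the 400 weight vectors, with
K ∈ {4, 6, 8, 10, 12, 16, 20} by default.  Class ids are relabeled in
decreasing order of protocluster count so that label 1 is always the
largest class; this makes labels comparable across runs without implying
any anatomical identity.  The K-means backend reassigns empty clusters
internally, so every partition has exactly K non-empty classes; a
defensive reseed loop guards the (unreachable) empty-cluster case.

Distances are unweighted Euclidean in the normalized 6-D space at both
levels; normalization already puts channels on comparable scales.

## Label-fraction features

Every tumor voxel — at full native resolution, not the training lattice —
is painted with its BMU's K-class label.  With `p_k` the percentage of
tumor voxels labeled `k`, the per-subject feature is `log10(p_k + 10⁻²)`:
−2 for an absent class, 0 at p = 0.99 %, ≈2.00004 at 100 %.  The 10⁻²
offset is chosen against percentages (not fractions), so small-but-present
classes are spread out rather than collapsed toward the floor.

## Classification

A linear SVM (libsvm backend) is tuned per LOOCV fold by a two-step grid
search: a coarse sweep over C ∈ {2⁻¹⁵, 2⁻¹³, …, 2¹⁵} scored by stratified
5-fold inner-CV accuracy, then 9 log-spaced candidates spanning ×4 around
the coarse winner; exact ties break toward smaller C (flatter models).
The search and the optional age standardization see only the training
fold, so no information about the held-out subject leaks into model
selection.  One ROC is built from the n pooled held-out decision values —
the only well-defined ROC under LOOCV — and AUC is the all-pairs
concordance fraction with ties counted ½.  Zero-denominator metrics are
reported as NaN, never as silent zeros.  The positive class defaults to
wild-type; both orientations are computable and the decision values flip
sign accordingly.

Numerical choice: solver iterations are capped at 10⁵.  At very large C on
noisy data libsvm can spend minutes converging toward a solution that
model selection will discard anyway; the cap bounds grid-sweep time and
does not affect the selected models (large C only wins on separable data,
where convergence is fast).

## Statistical comparisons

K values are compared on bootstrap replicates: subjects are resampled with
replacement, stratified by genotype (each class at its original size, so
no replicate loses a class), and the *same* replicate sample is fed to
every K — matching isolates the K effect.  LOOCV inside a replicate treats
duplicated subjects as distinct resampled units, which makes replicate
scores optimistic relative to the original-sample LOOCV; the comparison
across K is unaffected because all K share the optimism.  Replicate
AUC/accuracy/F1 distributions enter a one-way fixed-effects ANOVA and
Tukey HSD over all K pairs.  If every replicate is identical in every
group (e.g. a perfectly separable cohort), an explicit "no difference"
outcome is reported instead of a 0/0 F statistic.

Per-label log-ratios are compared between genotypes with two-sided
Mann–Whitney U tests: exact enumeration when both groups have ≤ 25
subjects and the pooled sample is tie-free, otherwise the normal
approximation with tie correction.  A row that is constant across both
groups takes U = n₁n₂/2 and p = 1 by convention.  Benjamini–Hochberg
step-up correction is applied within each K's family of label tests, and
labels are flagged at adjusted p < α = 0.05.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, at
desk scale:

| parameter | default | rationale |
|---|---|---|
| n_subjects / class balance | 62, 33/62 wild-type | reference cohort composition |
| volume shape | 48³ voxels | a 60-subject cohort yields ~45–50k stride-4 brain voxels, enough to train 400 protoclusters while keeping runs in minutes |
| tumor radius | uniform 5–9 voxels | tumors of 500–3000 voxels, large enough for stable label fractions |
| focus fractions (hypermetabolic, perfusion) | wild-type (0.25, 0.15), mutant (0.05, 0.05) | wild-type tumors carry larger high-FDOPA and high-rCBV sub-volumes |
| noise SD | 0.15 per channel | ~15 % of the normal-brain level: compartments overlap but remain resolvable |
| T2–ADC noise correlation ρ | 0.7 | T2 and ADC are elevated together in edema; implemented by sharing a latent noise field between the two channels |
| age | wild-type N(58, 12), mutant N(45, 12), clipped to [18, 90] | wild-type patients are substantially older on average |

Geometry is deliberately minimal: a spherical brain, a spherical tumor
centered uniformly in the radius-eroded brain, and 6-connected focus blobs
grown inside the tumor.  Focus sizes are drawn Binomial(n_tumor_voxels,
fraction) before growing, so the empirical focus fraction is exactly a
binomial proportion around the class target.  Per-subject RNG streams are
split from the cohort seed by counter-based spawn keys, so any subject can
be regenerated independently of order.

What the generator does **not** emulate: anatomy (no tissue boundaries,
ventricles, or skull), partial-volume effects, spatial noise correlation,
bias fields, infiltrative tumor margins, and multi-focal disease.  Passing
tests on these cohorts therefore demonstrates the pipeline's mechanics —
normalization, quantization, labeling, nested evaluation, statistics — not
clinical performance; headline metrics on real cohorts cannot be
reproduced from synthetic data, and the package makes no such claim.

## Degenerate inputs and edge behavior

Empty tumor masks, all-zero channels, NaN features, lattices that miss the
mask, single-class training sets, and K exceeding the node count are all
rejected with named errors.  A feature table whose rows are all constant
produces a warning and a report whose undefined metrics are NaN.  A
tumor radius that cannot fit a volume dimension raises an error naming the
offending dimension.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run at reduced, fixed sizes
chosen as the package's own desk-scale study conditions: a 60-subject
48³ cohort (~45,000 sampled voxels) for the signal-recovery checks, a
50-seed batch of 12-subject 24³ null cohorts (10 SOM epochs, K = 8) for
the FDR-control check, and a bootstrap reduced to 8 replicates over
K ∈ {4, 8, 16} for the model-comparison demonstration.

## Known limitations

- Pooled LOOCV decision values are a biased ROC basis under the null: with
  a perfectly balanced cohort the training majority always opposes the
  held-out class, which can push null AUC far below 0.5.  With the default
  (slightly imbalanced) cohort composition the majority never flips and
  null AUC sits near chance.  This is a property of pooled-LOOCV ROC
  construction, not of the feature extraction.
- Label identities are ordinal by cluster size only; label `k` in one run
  has no correspondence to label `k` of a run with different data.
- The SOM grid, epochs, neighborhood schedule, and K-means restart policy
  are conventional defaults, exposed in the configuration; they are not
  claimed to be optimal for any particular cohort.
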