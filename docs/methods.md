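# Methods

This note records the modelling choices behind `spchlpa`: what is
computed, which conventions were fixed where several exist, what the
synthetic cohorts do and do not emulate, and the numerical decisions that
affect reproducibility.

## Feature extraction

Features are computed from in-mask voxels only; the volume-of-interest
crop (tight bounding box plus a 2-voxel margin) is a convenience and never
changes feature values. No resampling or intensity normalization is
applied: the method is meant to run on CT as acquired, and all grey-level
handling is explicit in the quantization step.

Quantization uses two independent channels over the same HU window
(default [-1000, 400], air to soft tissue):

- histogram channel, 256 levels - percentile features then live on a
  byte-like scale (75th percentile of a ground-glass lesion ~ 60-130);
- GLCM channel, 32 levels - keeps the 32x32 co-occurrence matrix well
  populated for lesions of a few hundred to a few thousand voxels.

Mapping is linear with round-half-up (`level = 1 + floor(t + 0.5)`), which
is deterministic across platforms; both channel settings, the window, the
entropy log base and the percentile method are configurable.

Histogram skewness and kurtosis use population central moments
(divide-by-n) in the non-excess Pearson convention (kurtosis of a normal
sample ~ 3). A constant sample returns 0 for both rather than 0/0.
Uniformity is the sum of squared bin probabilities over the channel's
levels.

The GLCM accumulates *horizontally adjacent* voxel pairs - the unit offset
along the in-plane column axis - counting a pair only when both voxels are
in-mask, adding each ordered pair to (i, j) and (j, i). With the symmetric
matrix, marginal means and variances of rows and columns coincide and the
information-measure features are well behaved. Feature conventions fixed
here:

- difference variance is the contrast variant (identical to contrast);
  among the several published variants this is the one whose row equals
  the contrast row in the cohort table the package reproduces;
- sum variance is centred on sum average (the sum-entropy-centred form in
  the original feature list is widely regarded as a typo);
- entropies are natural-log;
- correlation, IMC1 are 0 and IMC2 is 0 for a zero-variance (single-level)
  matrix; 0 log 0 = 0 throughout; IMC2 is clipped into [0, 1] before the
  square root;
- the "normalized" inverse-difference features divide |i-j| by the level
  count of the matrix.

A single-voxel lesion has no co-occurring pair and raises an error by
default; an opt-in fallback substitutes the single-cell diagonal GLCM
(energy 1, contrast 0).

## Cascade classifier

The design addresses two facts about the clinical problem: the cohort is
imbalanced (13 vs 49), and the majority class is heterogeneous - part of
the LPA group is confidently separable from SPCH while the rest overlaps
it. The root node removes the separable LPA; the leaf then solves a
smaller, more balanced problem.

*Root.* PCA is computed on the **unstandardized** feature covariance. The
large-magnitude GLCM features (cluster prominence, sum variance,
autocorrelation) carry almost all raw variance, so two components
typically explain more than 99% of it, and the gate effectively operates
on the intensity-scale axis of the data. (Standardized PCA is available as
a config flag.) A class-weighted linear SVM on the two scores supplies a
decision value; the threshold is then swept subject to the hard constraint
that every training SPCH stays on the forwarded side, maximizing the
number of LPA picked out. All thresholds between the highest picked-out
LPA and the lowest SPCH decision value are equivalent under that
criterion; the implementation takes the **midpoint** of that interval.
This max-margin tie-break matters in leave-one-out evaluation: pinning the
threshold exactly at the training-SPCH minimum would gate out the held-out
minimum-score SPCH in its own fold almost surely, costing about 0.05 AUC
per occurrence at this cohort size.

*Leaf.* Exactly two features, chosen by plain greedy forward selection
(not the floating variant) with leave-one-out balanced accuracy of the
node classifier as criterion and canonical-order tie-breaking; restricting
the leaf to two features guards against overfitting at n ~ 30. The leaf is
trained on forwarded cases only (an all-cases option exists). Its decision
values are mapped to probabilities by a Platt-type sigmoid fitted as a 1-D
logistic regression; the slope is constrained non-negative so the
calibration is monotone toward SPCH.

*Classifiers.* Every node (and the baseline) uses the same margin
classifier: a linear hinge-loss SVM, cost C = 1, class weights inversely
proportional to class frequencies, inputs standardized within the node.
It is solved by deterministic dual coordinate descent (the liblinear
algorithm) compiled with numba, with the bias absorbed into an appended
constant feature. The custom solver exists purely for speed: the wrapper
feature selection evaluates a leave-one-out criterion for every candidate
feature in every outer fold (~10^5-10^6 SVM fits per cohort evaluation),
which general-purpose SVM bindings cannot sustain on one CPU. Inside that
criterion the per-fold solution is warm-started from the full-data dual
solution with a small corrective-sweep budget; node models themselves are
solved to tight tolerance (1e-8). The solver agrees with a reference
libsvm linear SVC on separable data (checked in the test suite).

*Baseline.* The same features, one class-weighted linear SVM on 3-6
forward-selected features (growth stops when no candidate improves the
criterion), Platt-calibrated. It represents the generic one-stage
approach the cascade is compared against.

## Evaluation

Leave-one-out cross-validation refits the entire pipeline - PCA, root
threshold, feature selection, calibration - on every fold's n-1 cases.
AUC is the rank-based (Mann-Whitney) statistic with ties counted 1/2;
confusion metrics call SPCH when P is strictly greater than the threshold
(so a root-rejected case, P = 0, is always LPA at 0.5).

The correlated-AUC comparison follows the Hanley-McNeil construction: each
AUC's standard error from the area and class counts (Q1 = A/(2-A),
Q2 = 2A^2/(1+A)), and the correlation r between the two area estimates
looked up from a table indexed by the average within-class Spearman
correlation of the score sets and the mean area, with bilinear
interpolation and edge clamping. The published table itself is not
machine-readable from the source article, so the package embeds a
reconstruction computed once by Monte Carlo under the equal-AUC binormal
ROC model (3000 paired cohorts of 60+60 per grid cell, fixed seed,
monotonized along the correlation axis; generator script at
`scripts/make_hm_rtable.py`). Degenerate comparisons (identical scores, zero variance)
report z = 0, p = 1. Under pure-noise score pairs at 13/49 the test
rejects at ~5-8% for alpha = 0.05 - slightly anti-conservative, as
expected for a normal approximation with 13 positives.

Univariate cohort statistics use the classic mean-centred Levene test
(alpha = 0.05) to route each feature to a pooled or Welch t-test, two
sided, uncorrected for multiplicity - matching the reporting convention
of the clinical literature the package mirrors. Summary-statistics mode
evaluates the same t-tests from (n, mean, SD) triples so printed cohort
tables can be checked directly; with the published summaries it reproduces
the printed p-values to +/-0.002 (the rounding of the summaries is the
only slack).

## Synthetic cohorts

The generator emulates the *statistical geometry* of the clinical problem,
not lung anatomy. Each lesion is an ellipsoid (semi-axes 3-10 voxels on a
48^3 grid at ~1 mm spacing, matching 5-29 mm nodules) of smoothed Gaussian
texture in a noisy -850 HU background, with an optional brighter core.
Class profiles (defaults, HU):

| profile   | mean      | noise SD | smooth len | core                     |
|-----------|-----------|----------|------------|--------------------------|
| SPCH      | -700 +-38 | 115      | 0.8        | 55% chance, small, +280  |
| LPA easy  | -430 +-60 | 60       | 0.7        | always, large, +320      |
| LPA hard  | -810 +-30 | 60       | 1.2        | 10% chance, small, +160  |

Two thirds of LPA are "easy", one third "hard". Per-lesion lognormal
jitter on noise and smoothness (25-45%) reproduces the high within-class
heterogeneity of real ground-glass cohorts (coefficients of variation
above 30%) - without it single monotone features separate the classes and
a one-stage SVM is already perfect.

Design rationale: SPCH sits *between* the LPA subgroups in intensity
(consistent with its frequently part-solid appearance versus the
mostly pure-ground-glass LPA), so no monotone function of the
intensity-scale features ranks SPCH above both subgroups; the easy
subgroup is separable along exactly the axis the unstandardized-PCA root
gate sees, and the hard subgroup is distinguished by smoothness-family
features plus an intensity contrast whose *sign is flipped* relative to
the easy subgroup. A single linear model must compromise between the two
signs; the cascade does not - that asymmetry is what makes the
divide-and-conquer benefit demonstrable (30-seed mean LOOCV AUC ~ 0.96
cascade vs ~ 0.87-0.88 baseline at the defaults). At the defaults the seven
features that are significantly different between groups in the published
cohort show the same direction of difference here (higher autocorrelation,
correlation, sum average, sum variance, sum-of-squares variance and
uniformity in LPA; higher kurtosis in SPCH), on average over seeds.

What passing these tests does *not* show: robustness to scanner
variation, segmentation error, anatomical confounders (vessels, pleura),
or non-ellipsoidal morphology - none of which the generator models. The
synthetic design demonstrates that the implementation behaves as the
method intends under the cohort geometry it assumes, not that the method
generalizes clinically.

A no-signal control (all three profiles set to the SPCH parameters)
verifies that neither model shows spurious skill. Note that under this
control the out-of-fold AUC of both models sits slightly *below* 0.5
(~0.43 on average): leave-one-out with per-fold wrapper feature selection
is pessimistically biased under the null, because the selection chases
chance separations that reverse on the held-out case - a known artifact
of the protocol, not a defect of the implementation; the bias direction
is the opposite of optimism. The control cohorts also drive the
type-I-error calibration of the feature report: their labels are
exchangeable, so label permutations provide exact null replicates (200
are used, drawn across 30 control cohorts). On these heavy-tailed
radiomic features the Levene-gated t-test flags ~3% of features at
alpha = 0.05 - conservative relative to the nominal 5%, which the same
machinery attains on Gaussian features.

## Problem sizes and determinism

Replication experiments use 30 seeds per arm (signal and control), 500
pure-noise replicates for the correlated-AUC calibration and 200
permutation replicates for the feature report; a full acceptance run is
a few minutes on one CPU (the SVM inner loops are JIT-compiled, and the
leave-one-out selection criterion is warm-started). Every random draw flows from an explicit
integer seed through `numpy.random.default_rng`; per-lesion seeds derive
from the cohort seed via `SeedSequence`. All fits are deterministic
(fixed-order coordinate descent, SVD-based PCA with a sign convention,
canonical tie-breaks), so identical inputs and seeds give bit-identical
models and scores.

## Known limitations

- The GLCM uses the single horizontal offset by design; rotation-averaged
  or 13-direction 3D co-occurrence is out of scope.
- The r table for the correlated-AUC test is a binormal-model
  reconstruction; r is also measurable directly by bootstrap, which is
  deliberately not implemented (the tabulated method is the one being
  mirrored).
- Platt calibration on ~30-60 training cases is crude; probabilities near
  0/1 should not be over-interpreted.
- DICOM reading handles one uniform series per directory and applies
  rescale slope/intercept only; no orientation resampling is attempted.
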