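# Methods

## Synthetic cohort model

Each subject's 4D volume is generated voxel-wise as

    x_v(t) = √ρ · s_r(t) + √(1−ρ) · e_v(t) + β_v · t

with one latent series s_r per effect region (plus one cohort-background
latent), private noise e_v per voxel, and a per-voxel drift slope β_v drawn
uniformly from `drift_slope_range` (default ±0.02 signal units per volume).
Both s and e are AR(1) processes with unit marginal variance (innovation SD
√(1−a²), a = `ar1_coef`, default 0.3 — serial correlation at the level the
rank statistic is sensitive to, without modeling the full BOLD spectrum).
Because the two components are independent with unit variance, the expected
correlation between any two voxels of a region is exactly ρ before drift,
so the between-group ReHo ordering is known analytically and the
calibration is testable (mean neighbor correlation within ±0.05 of ρ over
20 subjects). A single latent per region (rather than per neighborhood) was
chosen precisely for this closed-form calibration; its cost is that
synchrony is uniform across a region, unlike real cortex.

Random draws are ordered so that the group enters only through the mixing
weight √ρ: two subjects with the same seed but different groups share
latents, noise, and drift. Cohorts derive per-subject seeds from one
`SeedSequence`, making them bit-reproducible.

Cohort defaults are a balanced two-group study of 40 + 40 subjects with 200
retained volumes, 3 mm isotropic voxels, ages drawn from overlapping
normals (patients 25.95 ± 6.48 vs controls 24.80 ± 3.35 years, truncated at
18), 35% female in both groups, and LSAS scores drawn higher in patients
(total 65.42 ± 21.23 vs 33.80 ± 22.01; fear and avoidance subscales
likewise), all clipped at 0. The grey mask is the grid minus a 1-voxel
border, so by default every in-mask voxel has a complete 27-neighborhood and
edge-policy behavior is exercised only through custom masks.

What the generator does **not** emulate: spatial autocorrelation beyond the
injected regions, anatomical structure, rigid-body motion of image content,
physiological (cardiac/respiratory) noise, slice-timing offsets, or any
spatial normalization error. Passing tests therefore demonstrate that the
pipeline recovers the statistical structure it assumes — group differences
in local temporal synchrony under drift and serial correlation — not that
it would achieve any particular accuracy on clinical data.

## ReHo

Kendall's W uses midranks on ties and the tie-uncorrected denominator
K²(n³−n), the convention of the original ReHo formulation and the field's
standard tools; continuous BOLD data makes ties measure-zero, and a
constant series receives equal midranks (lowering W, never producing NaN).
Detrending (removal of the OLS line, per voxel) precedes ranking, matching
the usual preprocessing order. The vectorized implementation (rank volume,
27 shifted additions) is held to the naive per-voxel loop at 1e−12 on
volumes up to 10×10×10×50.

**Edge policy.** The neighborhood is the stencil intersected with the mask;
W is computed over however many in-mask neighbors remain (minimum 2), which
keeps the cortical rim rather than discarding it. `edge_policy="full"`
restricts to complete stencils for strict comparisons. Out-of-mask and
undersized voxels carry NaN in memory and 0 + mask on disk, so a computed 0
is never confused with background.

**Smoothing** acts on the finished ReHo map (not the raw series), with
σ = FWHM/(2√(2 ln 2))/voxel-size per axis and a kernel truncated at 4σ.
The default is receiver-renormalized masked convolution —
smooth(f·m)/smooth(m) — whose weights sum to 1 at every output voxel, so a
constant map is an exact fixed point and nothing bleeds in from background.
Total mass is preserved exactly only where the kernel support stays inside
the mask (interior impulses to 1e−6); near the mask boundary renormalization
trades mass preservation for constant preservation, which is the right
trade for a ratio statistic like W. Whole-volume smoothing is available as
a switch since the reference preprocessing chain does not document its
masking.

**Motion QC** passes a trace iff every translation column stays within
±1.5 mm and every rotation column within ±1.5° — inclusive at the limit,
reading "at the threshold" as the allowed extreme. The pipeline excludes a
QC failure together with its pair mate to preserve balance.

## MVPA

Features are the in-mask ReHo values; voxels missing for any subject are
dropped cohort-wide (logged) so all subjects share one column space. No
per-feature scaling or kernel normalization is applied by default — nothing
in the reference analysis indicates any — but per-subject L2 normalization
is available (`normalize: l2`) since the original toolchain's convention is
unpublished.

The SVM is solved in the dual by libsvm (scikit-learn `SVC`,
`kernel="precomputed"`) with tolerance 1e−9 so KKT conditions hold to
~1e−6; decision values are checked against an independent primal
quadratic-program solver (hinge loss with slack variables,
representer-parametrized w = Xᵀβ, scipy `trust-constr`) to 1e−4. C stays at
1 throughout; there is no hyperparameter search or feature selection.

**Pairing** for leave-one-pair-out is patient-k ↔ control-k in phenotype
row order unless a `pair_id` column supplies an explicit matching; the
matched-pairs design itself is assumed, the matching rule is not published.
A decision value of exactly 0 predicts the control class (deterministic,
logged). The test margin divides by ‖w‖ = √(aᵀKa) computed in kernel space.

**Permutation scheme.** The whole cohort is relabeled at once (a random
permutation of the label vector, preserving group sizes), the pairing is
re-derived on the permuted labels, and the entire cross-validation is
re-run — per-fold relabeling would break exchangeability of the held-out
labels. p-values use the add-one estimator (1+b)/(1+m), bounded below by
1/(m+1). The primary p is on accuracy; sensitivity, specificity, and a
joint rule (both sensitivity and specificity exceeded) are also reported
because the informal description of "higher sensitivity and specificity"
is ambiguous between an AND criterion and two tests.

**Discrimination map.** The default is the mean over folds of each fold's
unit-normalized weight vector; a map from a single model trained on all
subjects is the configurable alternative (`weight_map: full`). Which of the
two the original toolchain displayed is not documented; the fold average is
the more conservative summary of what the cross-validated classifier
actually used. Thresholding keeps |w| ≥ fraction · max|w| (inclusive, on
magnitude — both signs are reported, positive identifying patients),
clusters by 26-connectivity, and reports each cluster's peak voxel in index
and affine-mm coordinates. Anatomical labeling is out of scope.

ROC curves use the signed margins as scores with trapezoidal AUC;
all-identical margins degenerate to AUC 0.5 with a warning.

## Cohort statistics

The two-sample t is the classical pooled-variance Student's t (Welch by
flag); computed identically from raw vectors or (n, mean, SD) summaries, so
printed tables can be re-analyzed directly. On the reference age summaries
pooled and Welch agree to the printed precision. The 2×2 sex comparison is
Pearson's chi-square without Yates correction (with a perfectly matched
table the statistic is 0 either way). The margin–symptom correlation is
Pearson by default with Spearman alongside, and is computed both for
patients only and for all participants — the source analysis is ambiguous
on both choices, so the pipeline emits all four combinations per score. No
multiple-testing correction is applied across the three LSAS scores.

## Problem sizes and calibration checks

The test suite and acceptance script use desk-scale cohorts chosen so
Monte-Carlo checks are stable: null calibration uses 200 replicate
no-effect cohorts (10 per group, 8×8×8 grid, 60 time points) and verifies
mean CV accuracy 0.50 ± 0.05 and a 5% ± 3% rejection rate at α = 0.05 with
99 permutations; effect recovery uses ρ = 0.8 vs 0.0 in a 5³ region (10
per group, 200 time points), expecting perfect accuracy, permutation
p ≤ 0.01, and Dice ≥ 0.5 between the thresholded map and the injected
region; the monotone accuracy-vs-ρ trend uses 20 seed-paired replicates
across ρ ∈ {0, 0.3, 0.6, 0.9}.

## Known limitations

- The generator's spatial structure is far simpler than real grey matter;
  classification accuracies on synthetic cohorts say nothing quantitative
  about clinical accuracy.
- Masked smoothing preserves the in-mask mean only approximately near mask
  boundaries (exact for constants; 1e−6 for interior-supported maps).
- Unbalanced cohorts are rejected rather than handled; trimming or an
  unbalanced CV scheme is left to the user.
- Preprocessing that requires real scanner data (slice timing, realignment,
  spatial normalization) is out of scope; volumes are assumed already
  aligned to a common grid.
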