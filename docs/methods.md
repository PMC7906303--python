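# Methods

## Problem setting

Given n subjects described by D real-valued features and a binary group label
(+1 "positive", e.g. fall-prone patients; −1 "negative"), the package tests
whether the two groups differ *at all* in the joint feature space.  Classical
practice runs one univariate test per feature and applies a family-wise error
(FWER) correction; with D in the tens and modest n this is underpowered and
invites contradictory conclusions.  The package's core is a classifier
two-sample test: if any classifier can rank held-out positives above held-out
negatives better than chance, the distributions differ.

## The ts-AUC test

A random-subspace forest of T decision trees is grown: tree t draws a
bootstrap resample of the n subjects (with replacement, size n) and an
independent uniform subset of M features, then grows greedy binary Gini
splits over those M features until a minimum leaf size LS binds or a node is
pure.  Because the bootstrap leaves each subject out of a tree with
probability (1 − 1/n)^n ≈ e⁻¹ ≈ 36.8%, every subject is out-of-bag (OOB) in
roughly a third of the trees.  Subject i's score is

    P_i = mean over {t : i ∉ bag(t)} of  p̂_t(i),

where p̂_t(i) is the positive-class fraction, with bootstrap multiplicities,
of the in-bag subjects in the leaf of tree t that subject i reaches.  The
scores are internally cross-validated: no tree that saw subject i contributes
to P_i, so no data splitting is needed and every subject is scored.

The Mann-Whitney statistic U counts pairs (i ∈ positives, j ∈ negatives) with
P_i > P_j (ties ½), and AUC = U / (N₊ N₋).  The procedure is:

1. **Grid search.** For every (LS, M) with LS ∈ {8, …, 19} and
   M ∈ {1, …, min(8, D)}, fit a forest, compute the OOB AUC.  The grid is
   exhaustive (≤ 96 points); ties at the argmax break toward the simpler
   model (larger LS, then smaller M).
2. **Refit and test.** Refit a fresh forest (new seed) at (LS\*, M\*), compute
   its OOB posteriors P\*, and return the one-sided Mann-Whitney-Wilcoxon
   p-value for H₀: AUC\* = ½ against H₁: AUC\* > ½.

The p-value uses the exact MWW null distribution when N₊N₋ ≤ 400 and the
scores are tie-free, otherwise the normal approximation with tie and
continuity corrections.  Selecting hyperparameters on OOB AUC and then
testing on a refit's OOB scores re-uses the data; the type-I error of the
composite procedure is checked empirically (see below) and is conservative
in practice, because OOB posteriors are biased *against* a subject's own
class under the null (each subject is scored by trees trained without it).

Defaults: T = 200 trees; grid as above.  The benchmark studies in this
repository run at T = 100, the package's chosen study size: T enters only
through the Monte-Carlo averaging of leaf posteriors, and at T = 100 each
subject is already scored by ≈ 37 trees.  A without-replacement variant holding out an exact e⁻¹
OOB fraction per tree is available (`fit_forest(..., bootstrap=False)`) for
sensitivity analysis.

Subjects that are OOB in zero trees (probability ≈ (1 − e⁻¹)^T, negligible
at T ≥ 100) are flagged NaN and excluded from U with a warning.

## Feature importance and nested selection

For feature j, only trees whose feature subset contains j qualify.  For each
qualifying tree the OOB misclassification error (0/1 loss; a leaf fraction
> 0.5 classifies positive) is computed before and after permuting column j
among that tree's OOB subjects (one permutation per tree by default,
`n_repeats` to average more).  With d_j the mean error increase and σ_j its
standard deviation across qualifying trees, the importance is I_j = d_j/σ_j.
Features used by no tree are flagged undefined and excluded from the
ranking; σ_j = 0 with d_j = 0 gives I_j = 0, σ_j = 0 with d_j ≠ 0 gives a
signed sentinel (only possible in tiny forests).  Ranking ties break by
feature index.

"Model error" here is per-tree OOB misclassification rather than an
AUC decrease: the importance average runs over trees, which requires a
per-tree error, and 0/1 loss is the classical choice.  Importance is exactly
invariant under positive affine rescaling of features.  Under general strictly
monotone transforms the split *partition of the training points* is
preserved, but thresholds are midpoints between training values, so held-out
OOB points falling between the two straddling training values can switch
sides; exact invariance therefore holds for affine maps only, and this is
what the tests assert.

For interpretation, a nested-model curve is computed: for k = 1..D, fit R
fresh forests (default R = 20) on the top-k ranked features with LS = LS\*
and M = min(M\*, k), and record the mean and sd of the OOB AUC.  The selected
model is the smallest k whose mean reaches (max over k of the mean) minus
the sd at that argmax.  On the 30-dimensional benchmark below this reliably
keeps all designed features; it also tends to keep a few null features,
because adding harmless columns decorrelates the trees and nudges the OOB
AUC up slightly — the rule is intentionally inclusive (interpretation, not
parsimony).

## Baselines

* **Univariate screen**: two-sided MWW per feature; corrections Bonferroni,
  Holm, Hochberg and Hommel (via statsmodels).  The screen is two-sided while
  the ts-AUC alternative is one-sided; the asymmetry mirrors how each is
  used (exploratory screening vs a directional separability test).
* **MMD**: unbiased squared maximum-mean-discrepancy U-statistic with a
  Gaussian kernel, bandwidth h = median pairwise Euclidean distance of the
  pooled sample (configurable), p-value from B label permutations with the
  statistic recomputed on the fixed kernel matrix; add-one estimator
  (b + 1)/(B + 1), default B = 1000.

## Synthetic data

The generators define the benchmark conditions:

* `simulate_gaussian_groups`: two independent Gaussian groups in D
  dimensions; a fraction (default ⅓) of the dimensions — always the *last*
  ones in index order — has mean `delta` in the positive group, all other
  entries are N(0, 1).  Exactly round(pos_fraction·n) positive labels.
* `simulate_importance_design`: n subjects, 50/50, D = 30; columns 1–22 are
  N(0, 1) in both groups, columns 23–30 are N(0.9, 1) in the positive group;
  columns independent.
* `simulate_cop_trajectory`: a discretized Ornstein-Uhlenbeck walk per axis
  (exact transition, started from the stationary law), default 25 s at
  25 Hz (625 samples), reversion rate 1 s⁻¹ and diffusion scale 0.5 cm·s^-½
  per axis, giving a stationary sway s.d. of ≈ 0.35 cm — a plausible
  quiet-standing magnitude.  A `group_effect` factor scales the
  antero-posterior diffusion, emulating the larger AP variance/velocity of
  fall-prone subjects.  The stationary variance sd²/(2·reversion_rate) is
  closed-form, which is what makes the generator a usable oracle.  The
  generator emulates only second-order sway statistics; it has no tremor
  spectrum, drift, or non-stationarity, so passing tests validate the
  *feature algebra and test calibration*, not clinical realism.

## Posturographic features

Seventeen standard center-of-pressure features per recording (x =
medio-lateral, y = antero-posterior, cm; uniform sampling required — inputs
off by more than 1% from 1/fs are rejected rather than resampled).  The
quantities without a universally fixed formula use these declared dialects:

* Velocity/Acceleration: mean **absolute** first/second finite difference
  times fs / fs² (a signed mean is ≈ 0 for any bounded trajectory and
  useless as an impairment marker).
* F95: smallest one-sided raw-periodogram frequency at which cumulative
  power reaches 95% of the total over (0, fs/2], after mean removal, DC
  excluded; constant series → 0 Hz.
* DistC: mean Euclidean distance to the trajectory centroid (the sample mean
  point, not the platform origin — it is a dispersion measure).
* EllArea: π·c·√det(Σ̂) with Σ̂ the 2×2 sample covariance and c = 5.991 the
  95% chi-square quantile (2 d.f.); degenerate covariance → 0 with warning.
* AngularDeviation: mean absolute turning angle between consecutive nonzero
  displacement steps, in degrees.

All features are invariant to translation (except Max/Min, which shift) and
time reversal; under coordinate scaling by k, lengths scale by k, variances
and areas by k², F95 and angles not at all.  These are asserted as tests.

## Benchmark problem sizes

The repository's Monte-Carlo studies use: type-I calibration at n = 100,
D = 30, 500 replicates, T = 100 trees; power ordering at n = 200, D = 30,
δ ∈ {0.3, 0.6, 0.9}, 20 runs per cell; importance recovery at n = 200, 10
seeds, nested selection with R = 20 runs.  These sizes give Monte-Carlo
standard errors comfortably below the margins being asserted while keeping
the full suite fast to re-run.

## Numerical and design choices

* Splits require a strictly positive Gini gain (> 1e-12); both children must
  satisfy the minimum leaf size; candidate thresholds are midpoints between
  consecutive distinct sorted values.  Equal-gain ties resolve to the first
  (lowest-index) feature and lowest threshold — deterministic.
* All randomness flows through `numpy.random.SeedSequence`: per-tree seeds,
  per-grid-point seeds, and per-(cell, repeat) experiment streams are spawned
  from the caller's single seed, so every result is bit-reproducible and
  cells can be parallelized without changing numbers.
* The hyperparameter search is an exhaustive grid rather than a surrogate
  optimizer: the space has at most 96 points, so exhaustive search is both
  cheaper and deterministic.
* Subject order is not a stable identity: permuting the rows of a table
  changes which bootstrap draw hits which subject, so results are
  reproducible for a fixed table, not invariant to row shuffles.

## Known limitations

* Correlated/redundant features split importance between them; the nested
  rule keeps redundant relevant features by design but offers no conditional
  importance.
* The classifier two-sample test is one-sided by construction (separability
  only); it cannot say *which* marginal differs — that is what the
  importance report is for.
* OOB-based calibration is slightly conservative under the null; power
  comparisons against MMD should be read with that in mind.
* With extreme class imbalance (minority ≲ 20) both the forest posteriors
  and the simulated minority group are unstable; results there are
  qualitative at best.
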