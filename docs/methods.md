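# Methods

This note documents the models, statistics, numerical choices and known
limitations behind `gaitsym`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Problem setting

Healthy walking produces a characteristic vertical ground-reaction-force
(vGRF) curve over the stance phase: a loading-response peak (Fz1, ~114 %BW
near 23 % of stance), a mid-stance valley (Fz2, ~75 %BW near 49 %), and a
push-off peak (Fz3, ~110 %BW near 77 %). Gait symmetry asks whether the
left and right limbs produce the same curves. `gaitsym` implements and
contrasts two answers:

1. **The classical protocol** — reduce each curve to the six discrete
   parameters (Fz1, Tz1, Fz2, Tz2, Fz3, Tz3), then per parameter compute
   the trial-to-trial coefficient of variation CV = SD/mean x 100
   (repeatability accepted at CV <= 12.5 %), Robinson's absolute symmetry
   index SI = 2|X_R - X_L| / (X_R + X_L) x 100 (symmetry accepted at
   SI < 10 %), and a two-sided paired t-test of left vs right across
   subjects (difference declared at p <= 0.05).
2. **Symmetry as classification** — treat each 101-point normalized stance
   curve as one sample of a left (-1) or right (+1) class and train a
   soft-margin kernel SVM to tell the sides apart. If the two sides share a
   distribution, no classifier can beat chance; cross-validated accuracy
   above 0.5 is therefore evidence of asymmetry, and its permutation
   distribution under within-subject label swaps yields a calibrated
   p-value.

## Preprocessing

Raw trials are force time series in Newtons at a fixed sampling rate
(default 400 Hz). The pipeline:

* **Bodyweight normalization**: samples x 100 / bodyweight, giving %BW, so
  Fz1 ~ 114 means 114 % of bodyweight.
* **Negative clipping** (default on): vertical GRF is physically
  non-negative; negative sensor noise is clipped to 0. Configurable off.
* **Stance segmentation**: the longest contiguous run of samples at or
  above a threshold (default 5 %BW), extended by one sample on each side so
  the curve re-enters the near-zero flanks. The threshold is a convention,
  not physiology; force-platform practice uses 5-20 N equivalents. Runs
  shorter than 4 samples are rejected.
* **Time normalization**: piecewise-linear interpolation of the stance
  segment onto 101 equally spaced points over 0..100 % of stance duration
  (1 % spacing, endpoints preserved exactly). Linear interpolation is
  parameter-free and monotonicity-preserving; at 400 Hz and ~0.7 s stances
  its error is far below the trial-to-trial variability of the signal.

One terminology note: recordings from a single embedded platform cover the
stance phase only, so "the gait cycle of each limb" is operationalized as
that limb's stance phase; the 101-point grid spans stance, not the full
stride.

## Discrete parameters and PCA features

Peak extraction searches window [5 %, 40 %] for Fz1 and [60 %, 95 %] for
Fz3 (wide margins around the physiological timings above; configurable),
then takes the minimum strictly between the two peak times as Fz2. Ties
break to the earliest index. A curve whose "valley" exceeds a peak (e.g. a
unimodal curve) is rejected as non-M-shaped rather than silently
parameterized.

PCA features are computed by mean-centering and eigendecomposition of the
sample covariance (n-1 denominator, full SVD). The number of retained
components is the smallest k whose cumulative explained-variance fraction
reaches `variance_fraction` (default 0.95). There is no canonical number of
components for gait curves; the cumulative-variance rule is the standard
default and is exposed as a parameter. Inside cross-validation the PCA
basis (like feature standardization) is fitted on training folds only and
frozen for the test fold — fitting on all data would leak test information
into the representation.

## The SVM and its solver

The classifier is the standard two-class soft-margin SVM. Primal:
minimize ||w||^2/2 + C sum xi_i subject to y_i (w.phi(x_i) + b) >= 1 - xi_i,
with hinge slack (penalty exponent 1). It is trained through the dual

    max  W(beta) = sum beta_i - 1/2 sum beta_i beta_j y_i y_j K(x_i, x_j)
    s.t. sum beta_i y_i = 0,  0 <= beta_i <= C,

with kernels linear `x.z`, polynomial `((x.z)+1)^d`, and Gaussian RBF
`exp(-||x-z||^2 / (2 sigma^2))`. The RBF exponent is negative — the only
sign under which the expression is a Mercer kernel and the exponential
bounded.

**Solver.** Sequential minimal optimization with most-violating-pair
working-set selection: the first index maximizes the KKT violation over the
"up" set, the second is chosen by the second-order rule (largest guaranteed
dual decrease along the pair direction). Each pair is solved analytically
under the equality constraint and clipped to the box; the dual objective is
recorded after every step and is non-decreasing by construction. Iteration
stops when the violation gap falls below `tolerance` (default 1e-3) or
after `max_passes * n` pair updates. The bias is recovered afterwards as
the mean of -y_i * grad_i over free support vectors (midpoint of the
feasible interval when no beta is free). This selection rule is
deterministic, which makes every seeded run bit-reproducible; `train_svm`
accepts a `seed` argument for interface stability. Degenerate pair
curvature (duplicate points, rank-deficient linear kernels) is floored at
1e-12, which reduces the step to a safeguarded endpoint move.

**Standardization.** Polynomial and RBF kernels are scale sensitive, so
features are standardized to zero mean and unit variance by default, with
constants fitted on the training set only; zero-variance features keep
scale 1. Disable with `standardize=False` for geometric toys.

Ties at the decision boundary (f(x) = 0) predict +1; documented, and only
reachable on constructed inputs.

## Cross-validation design

The default experimental unit is one pattern per subject per side — the
mean of that subject's trials — so a 60-subject cohort gives 120 patterns
(60 per class). Balanced k-fold cross-validation (default k = 6, repeated
10 times with fresh shuffles) puts exactly n/k patterns of each class in
every fold. By default both sides of one subject stay in the same fold
("subject-paired"): splitting a subject across train and test would let the
classifier recognize the subject rather than the side. A "pattern-level"
mode that stratifies only by class is provided for comparison, as is a
per-trial mode that skips trial averaging. Metrics are computed per fold
from the confusion table (right = positive class): accuracy,
sensitivity = TP/(TP+FN), specificity = TN/(TN+FP); undefined ratios are
reported as NaN with a flag, never as silent zeros.

The grid search evaluates kernel x C x feature-mode combinations through
exactly this machinery and ranks by mean accuracy with ties broken by
sensitivity, then specificity, then smaller C (prefer the less complex
model). Hyperparameters selected this way are optimistic for the winning
cell — there is no nested CV — which mirrors the common single-loop
protocol; treat the best-cell accuracy as descriptive, not as an unbiased
generalization estimate.

## The symmetry score and permutation test

`symmetry_score` maps mean CV accuracy to `1 - 2 max(acc - 0.5, 0)` (1 =
chance = symmetric, 0 = perfectly separable = maximally asymmetric) and
attaches a permutation p-value: the left/right labels of each subject are
swapped with probability 1/2 (a draw from the exchangeable null that
preserves subject structure and class balance), the entire cross-validation
is re-run, and `p = (1 + #{permuted acc >= observed}) / (1 + n_perm)`. At
least 19 permutations are needed to resolve p <= 0.05; the default is 99.

## Synthetic cohorts

The generator emulates the statistical structure of a healthy force-platform
study, not the biomechanics of gait:

* **Waveform**: a monotone cubic (PCHIP) interpolant through
  (0, 0), (Tz1, Fz1), (Tz2, Fz2), (Tz3, Fz3), (100, 0). Monotone
  interpolation places the curve's interior extrema exactly at the six
  parameters, so generator truth maps one-to-one onto what extraction
  should recover — a closure property the tests assert. A sum-of-lobes
  form (e.g. Gaussians) was rejected: overlapping positive lobes with a
  lower middle lobe produce a local maximum, not a valley, at the middle
  center unless the peak lobes are made implausibly wide, and the realized
  extrema then drift from the nominal parameters. The PCHIP curve is smooth
  and M-shaped but carries no physiology beyond its extrema.
* **Population structure**: subject-level parameters are drawn around
  population means (defaults 114/75/110 %BW at 23/49/77 % stance) with
  between-subject CVs, and each trial jitters them multiplicatively with
  within-subject CVs. Multiplicative (CV-scaled) jitter is used because
  gait-parameter variability is conventionally reported as CV. Default
  per-parameter CVs are 8.7/9.2/6.9/5.4/8.6/4.4 % (Fz1/Tz1/Fz2/Tz2/Fz3/Tz3),
  the reported scale for elderly healthy walking; between-subject spread
  defaults to the same relative scale since only within-subject CVs are
  conventionally published.
* **Force correlation**: the three force amplitudes share a common loading
  factor with pairwise correlation 0.6 (marginal CVs preserved exactly).
  vGRF amplitudes rise and fall together with loading and speed; fully
  independent draws would make the valley collide with a peak in a few
  percent of draws, which is an artifact of the independence assumption,
  not of the data being emulated. Times are drawn independently.
* **Asymmetry**: per-parameter multiplicative deltas applied to the right
  side (e.g. `{"fz1": 0.05}` = right loading peak 5 % higher). Draws that
  leave the valid M-shape region (ordered times with 2 % margins, valley
  below 98 % of the lower peak, positive forces) are clamped; a warning
  fires when clamps exceed 1 % of draws *and* at least 10 draws clamped
  (clamps cluster on subjects near a boundary, so a raw rate test fires
  spuriously in small cohorts).
* **Rendering**: curves are sampled at the configured rate over a stance
  duration drawn per trial (0.7 +/- 0.05 s — the duration only enters
  through time normalization, so its distribution is inconsequential by
  design), converted to Newtons by a subject bodyweight (700 +/- 70 N),
  given additive white measurement noise (3 N), and padded with noise-only
  flanks so stance segmentation is exercised.
* **Reproducibility**: every subject consumes an independent random
  sub-stream of the master seed, so enlarging a cohort never changes
  earlier subjects' draws, and equal seeds give bit-identical cohorts.

What passing tests on these cohorts does **not** show: robustness to real
force-platform artifacts (drift, filtering, partial foot strikes, crosstalk),
to non-M-shaped pathological curves, or to asymmetries that change curve
*shape* rather than rescaling the six parameters.

## Scales used in the automated checks

The statistical checks in `tests/test_acceptance.py` and
`scripts/acceptance.py` run on reduced problem sizes chosen so the whole
suite completes comfortably on one CPU while keeping the binomial bands
meaningful: 12-subject cohorts (10 trials/side), 200 null cohorts for
calibration (pooled CV accuracy against the 99 % binomial band around 0.5;
paired-t significance rate against its band around 0.05), 15 cohorts per
asymmetry delta for the power curve, and 50 cohorts (49 permutations each)
for the detection-rate comparison. The asymmetry family for those checks is
an equal multiplicative delta on {Fz1, Fz2, Fz3, Tz2} — several parameters,
with magnitudes in the few-percent regime where the classical SI flag is
blind by construction (a 3 % shift yields SI ~ 3 %, far under the 10 %
line) while the mid-stance-time component is large relative to its ~5 % CV.
Tz3 is excluded so the same family remains valid up to delta 0.30
(1.3 x 77 % stance would leave the domain).

## Numerical conventions and edge cases

* Sample standard deviations use the n-1 denominator everywhere (CV,
  t-test, PCA eigenvalues).
* p-values are probabilities in [0, 1]; tabulated gait literature sometimes
  prints them as percentages.
* CV of a zero-mean sample, SI with X_R + X_L = 0, and paired differences
  that are constant and nonzero are domain errors, not numbers; identical
  paired sequences return t = 0, p = 1.
* The t-test is two-sided (sidedness is a convention; two-sided is the
  conservative default).
* SI aggregation: the default computes each subject's SI from that
  subject's side means and averages across subjects; `si_of_group_means`
  applies the formula once to group means. The two differ whenever
  subject-level asymmetries partially cancel — group-mean SI
  underestimates the typical per-subject asymmetry, which is why
  per-subject aggregation is the default.
* The six parameters are tested without multiple-testing correction,
  matching the classical protocol being reproduced; at six tests the
  family-wise false-positive rate is ~26 % under the null.

## Known limitations

* The SMO solver targets the n <= a-few-hundred regime of gait studies; no
  shrinking, caching or working-set generalization for large n.
* No probability calibration; the decision value is an uncalibrated margin.
* The permutation test re-runs the full CV per permutation — exact and
  simple, but the dominant cost of `symmetry_score`.
* The generator's six-parameter asymmetry cannot express shape changes
  (e.g. flattened valleys after joint replacement); a classifier advantage
  on such data is plausible but untested here.
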