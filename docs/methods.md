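# Methods

## Problem setting

A 96-electrode microelectrode array implanted in the hand area of primary
motor cortex records action potentials while a subject performs cued
finger movements: after a randomized 1,000–3,000 ms wait a visual cue
appears, the subject has up to 2,000 ms to close the cued switch and must
hold it for 500 ms. Ten movement types plus an explicit rest class give an
11-class decoding problem. Each electrode can pick up several neurons;
decoding can use the aggregate rate per electrode ("multi-unit" features)
or the rate of each isolated neuron ("single-unit" features). The package
asks which filter criterion should pick the feature subset fed to an SVM,
how many features are optimal, and how gracefully each criterion degrades
as chronically implanted arrays lose units.

## Why feature selection: curse of dimensionality

Two closed forms quantify the sparsity of fixed-size samples in high
dimension. The probability that a standard d-variate normal point falls in
the "mean ± 1 SD" ellipsoid (Mahalanobis distance ≤ 1) is the chi-square
CDF with d degrees of freedom at 1: 68.27% at d=1, 39.35% at d=2, 0.18% at
d=8. The axis-aligned convention (all coordinates in [−1, 1]) is
0.682689^d, about 5.1 × 10⁻⁹ at d=50. The expected nearest-edge distance
of n points in a d-dimensional unit hypercube is D(d, n) = ½·(1/n)^(1/d):
0.005 for (d=2, n=10⁴) and 0.45600 for (d=100, n=10⁴) — reported at two
decimals as 0.45, truncated rather than round-half, matching the
convention of the source the value is compared against. Both conventions
for the ±1 SD region are exposed because each reproduces a different
subset of the headline figures; the ellipsoid one is used for the
percentage curve.

## Synthetic sessions

No public recordings exist for this task, so the generator is first-class
and defines the study conditions.

* **Spiking model.** Each unit is an inhomogeneous Poisson process with a
  piecewise-constant rate: its baseline rate everywhere, multiplied by a
  per-class gain inside the movement window (450 ms before to 1,000 ms
  after switch closure). Implemented exactly by superposition (extra
  Poisson spikes for gain > 1) and thinning (gain < 1). This encodes the
  premise that movement information lives in firing-rate changes; it
  deliberately omits refractoriness, bursting, latency structure and
  non-stationary drift, so passing tests demonstrate correct pipeline
  behaviour under Poisson assumptions, not performance on real tissue.
* **Population.** Unit count per session is round(Normal(142.2, 36.3)),
  clipped below at the electrode count (a user-set count below it is a
  config error). Every electrode receives at least one unit and at least
  one electrode carries two or more. Baseline rates are Gamma(shape 2,
  mean 10 sp/s) — right-skewed, as cortical rate distributions are.
* **Tuning.** A fraction (default 0.2) of units is informative: per-class
  gains 1 + (effect_size − 1)·U(0, 1) with effect_size 3 by default.
  Multiplicative gains with a shared window are the simplest structure
  that makes all four criteria discriminative; real tuning shapes are
  unknown for this preparation.
* **Schedule.** Trials (trials_per_class per movement class, plus rest
  epochs that leave all units at baseline) are shuffled and spaced so the
  baseline window (2,500–1,000 ms before closure) of every trial is free
  of any movement window; reaction times are U(250, 800) ms within the
  2,000 ms limit.
* **Masking scenario.** `dominant_rate` adds one untuned unit at that rate
  (80 sp/s in tests) to every electrode, so electrode-level rates are
  dominated by untuned spiking while isolated units keep their tuning —
  the mechanism proposed for why single-unit features resist failure
  better.

## Rate estimation

Timestamps are binned at 600 Hz; a 300 ms boxcar stepped every 20 bins
(33.33 ms — the step is interpreted as exactly 20 bins so all decimation
ratios are integer) yields a 30 samples/s rate; a zero-phase 4th-order
Butterworth low-pass at 10 Hz (applied forward and backward, so the
effective attenuation is the squared magnitude response) precedes
polyphase resampling to exactly 20 Hz. The boxcar window is centred on the
output sample to avoid systematic lag. Negative filter ripple is clipped
to zero. Per trial, the movement epoch is 29 samples and the baseline
epoch 30 samples at 20 Hz. The default feature is the mean rate over the
epoch — one scalar per (trial, feature), which makes the optimal feature
count directly comparable to the unit count; the full 29-sample vector per
feature is available (`scalarize=False`) for sensitivity checks.
Multi-unit features merge an electrode's spike trains *before* rate
estimation; because the chain is linear apart from the final clip, the
multi-unit rate equals the sum of its constituent single-unit rates up to
clipping.

## Ranking criteria

All criteria rank best-first with ties broken by ascending feature index.

* **Wilcoxon signed-rank** on per-trial paired differences (movement mean
  minus same-trial baseline mean, movement trials pooled across classes;
  rest epochs excluded). Features kept only if p < 0.001 — a fixed screen,
  deliberately without multiplicity correction — with positive median
  difference, ordered by decreasing median difference. The kept list may
  be much shorter than the feature count, which caps this criterion's
  sweep.
* **Relative importance**: variance (denominator M−1) across movement
  classes of the class-mean movement-only rate.
* **PCA**: explained-variance-ranked principal components of the
  mean-centred matrix. It is a transform, not a subset selector —
  "selecting k features" means using the first k projections — and the
  loadings are re-fitted inside every training partition during
  cross-validation so test rows never influence them.
* **MIM**: plug-in mutual information I(C;Y) = H(C) − H(C|Y) in bits
  between the discretized feature value and the class label (rest
  included as its own class). Discretization is 10 quantile bins by
  default — robust to the right-skew of rates; equal-width binning is
  config-selectable.
* **Random**: seeded uniform permutation, the control.

## Decoding

One-vs-one decomposition: k classes give k(k−1)/2 binary soft-margin
RBF-SVMs, prediction by majority vote with vote ties resolved to the
lowest class index. The kernel is exp(−‖x−x′‖²/(2σ²)); σ and the box
constraint C are grid-searched over decadal values 10⁻⁵…10⁵ by default.
Features are z-scored with training-fold statistics. Accuracy is
estimated by stratified 10-fold outer cross-validation, the grid chosen by
3-fold inner cross-validation within each outer training partition, the
whole scheme repeated 20 times with re-randomized folds (all defaults of
`SVMConfig`). Rankings are computed once on the full session by default,
matching the original protocol; a stricter per-fold re-ranking mode
(`rank_in_fold=True`) recomputes them inside each outer training
partition and is what the chance-calibration tests use, since label-aware
criteria otherwise select spuriously coupled features using rows that
later serve as test rows. The feature-count sweep evaluates accuracy at
increasing counts and picks the smallest count attaining the maximum;
grid-search ties keep the first grid entry in iteration order. A single
stratified 70/30 holdout (`holdout_accuracy`) is exposed as a quick
alternative to the nested scheme.

## Failure and longevity protocols

Simulated failure removes raw features uniformly at random —
floor(level·p) survivors per retained-fraction level, the floor matching
the published survivor counts (9 of 96, 35 of 350 at 10%) — then re-ranks
and re-sweeps on the survivors, aggregating over dropout repeats
(20 by default). Dropping from the ranked list's tail instead is
config-selectable (`drop="tail"`). The longevity study runs the full
pipeline independently per session over a schedule of 47 sessions across
142 days by default, with unit count and effect size declining linearly
(to 50% and 70% of their starting values) as a stand-in for chronic
interface degradation, which is not quantified in the source material.
Summaries provide Bonferroni-corrected pairwise two-sample t-tests across
methods and Kruskal–Wallis tests across methods per failure level.

## Numerical and design choices

* Seeding: one master seed is fanned out by hashing stage tags
  (CRC32 into a `SeedSequence`), so adding a stage never perturbs the
  streams of existing stages; all outputs embed the config hash and
  master seed and are byte-reproducible.
* The chance level for k classes is reported as 1/k (9.09% for 11
  classes, even though "10 degrees of freedom" suggests 10%).
* Degenerate inputs: unsorted timestamps, zero-variance matrices for PCA,
  empty epoch sets, a class without trials, and fewer samples than MI
  bins all raise; all-zero paired differences exclude a feature from the
  Wilcoxon ranking rather than erroring.
* The binary SVM solver is delegated to libsvm (scikit-learn); the
  one-vs-one vote counting and tie-break live in this package because
  libsvm resolves vote ties by aggregated confidence rather than lowest
  class index.

## Test problem sizes

The default `SVMConfig` encodes the full protocol; the test suite runs
deliberately smaller designs chosen to keep each check sharp at suite
scale: chance calibration uses a 30-unit session with 10 trials per class
and averages 20 independent label permutations (one nested-CV run each);
planted recovery uses 30 units, 20% informative, effect size 3, 100
trials per class, 20 session seeds; the masking study uses 8 electrodes ×
(2 regular + 1 dominant) units, 5 movement classes, retention levels
100/60/30% with 4 dropout repeats and 20 session seeds; reduced σ/C
subgrids are used throughout the tests. These sizes are package choices
recorded here so the tests are interpretable; the library accepts the
full-scale settings unchanged.

## Known limitations

* PCA's planted-recovery check is necessarily defined at the transform
  level (share of between-class variance captured by the top-20%
  subspace): unsupervised components cannot be mapped one-to-one onto
  units, and low-baseline tuned units are legitimately under-represented
  in a variance-ranked basis.
* Plug-in MI is upward-biased at small sample counts; rankings are
  unaffected because the bias is shared across features of a table.
* The Poisson generator cannot exhibit the slow covariate drift, unit
  splitting/merging, or correlated noise of chronic recordings, so
  longevity results characterize the pipeline, not biological stability.
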