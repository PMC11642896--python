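# Methods

`cardioresp` implements an end-to-end pipeline for classifying the health
status of pediatric subjects (Cardiac / Healthy / Sport) from short static
cardiorespiratory recordings, with the cardiorespiratory-coupling (CRC)
features of the causal and information domains as its methodological core.
Because no public recording set exists for this problem, the package ships
a first-class synthetic cohort generator with known ground-truth coupling;
every downstream stage is validated against that ground truth.

## Synthetic cohort generator

**Respiration.** Each breath is a raised-cosine inspiration followed by a
raised-cosine expiration; the inspiration fraction is `ie/(1+ie)` of the
breath (default I:E = 0.7, a typical resting value). Per-breath amplitude
jitter (lognormal-like, 10%) emulates tidal-volume variability. Breath
rates have two variance components: a between-subject rate drawn from a
truncated normal matched to the group's published mean, SD and range, and
a within-recording per-breath jitter with SD `0.5 x resprate_sd`. The
detected respiratory rate (60 / mean breath duration) is the *harmonic*
mean of per-breath rates and is biased low by roughly `(sd/rate)^2`; the
per-breath draw location carries an explicit harmonic-mean correction so
that detected rates are unbiased. Waveform spectral power is concentrated
inside the 0.05–0.67 Hz physiological band by construction.

**RR intervals.** Beat `n` at time `t_n`:

    RR_n = mu_RR + a * v_n + g * r(t_n - lag)   [ms]

`mu_RR = 60000 / HR`, `r` is the standardized respiration waveform sampled
at the lagged beat time (lag default 0.4 s, inside the ±1 s physiological
window), and `v` the intrinsic variability. Two intrinsic modes exist:

* `ar1` (default) — unit-variance AR(1), coefficient 0.8: broadband
  short-memory variability; the simplest mechanism with tunable
  RSA-like directional coupling.
* `pseudo_resp` — an *independent* respiration-like waveform sampled at
  beat times: spectrally matched to the coupled term. Used to build
  coupling-only group contrasts (below).

The scales `(a, g)` are calibrated per preset so that the expected RMSSD
hits the group target and the respiratory share of RR variance equals the
preset `coupling_strength` (`a^2 ∝ 1-c`, `g^2 ∝ c`). Calibration uses a
closed-form initialization (AR(1) increment variance `2(1-phi)` and the
empirical beat-scale diffusion of the respiration waveform) followed by
Monte-Carlo pilot refinement; it is deterministic given its seed, and a
`CalibrationError` carries the achieved values if the 5% RMSSD / 0.05
variance-share tolerances cannot be met. `coupling_strength = 0` forces
`g = 0`, giving every causal estimator an exact null.

**Subjects and demographics.** Per-subject HR, RMSSD and respiratory rate
are drawn from truncated normals over the published group ranges whose
location is solved (Brent's method) so the *truncated* mean equals the
published group mean — naive truncation of the wide right-skewed RMSSD
distribution would bias the group mean by about +10%. Age, body mass and
height are plain truncated normals per group; sex is Bernoulli with the
group's published male fraction (the Sport group is all male); BMI is
derived. Group presets default to the published descriptive statistics
(HR 72.8/79.4/76.9 beats/min, RMSSD 55.3/61.8/68.2 ms, RespRate
18.5/18.8/17.1 breaths/min for Cardiac/Healthy/Sport) with coupling
strengths 0.2/0.5/0.7 as configurable separability knobs — the real
group-wise coupling is unknown, so synthetic separability is a modelling
choice, not a physiological estimate.

**What the generator does not emulate:** ectopic beats and artifacts
(the target pipeline assumes physician-corrected RR series), raw ECG
morphology, baseline wander and electrode noise in the impedance signal,
age/maturation trends in HRV, and the heterogeneity of cardiac diagnoses.
Passing tests therefore demonstrate correctness of the estimators and
pipeline mechanics under a controlled RSA-like mechanism, not clinical
performance on real recordings.

## Preprocessing

Respiration is band-passed to 0.05–0.67 Hz (3–40 breaths/min) with a
4th-order Butterworth applied forward-backward; zero phase protects the
lag-sensitive coupling features. RR stationarity is checked with a
Phillips–Perron Z_tau test (Newey–West/Bartlett long-run variance, lag
truncation `4(n/100)^(2/9)`, MacKinnon p-values); the result is logged,
not fatal. RR intervals are cubically interpolated onto a uniform grid
spanning first to last beat (the tachogram, 250 Hz), and both signals are
decimated to 25 Hz (zero-phase FIR anti-aliasing) for the coupling block.

## Feature battery (157 features)

5 demographic (age, weight, height, sex, BMI), 102 cardiac, 18
respiratory, 32 causal/information. The cardiac battery covers time-domain
statistics (30), Welch band powers of a 4 Hz-resampled tachogram with
120 s segments and 50% overlap (16; LF 0.04–0.15 Hz, HF 0.15–0.4 Hz),
Poincare geometry, heart-rate asymmetry and fragmentation (27), entropy
and fractal measures (17; sample/approximate/fuzzy/permutation entropy
with m=2, r=0.2·SD, DFA alpha1/alpha2, Higuchi/Katz/Petrosian/Sevcik
dimensions, Lempel–Ziv, rescaled-range Hurst), and symbolic dynamics (12;
6 equal-width bins over mu±2sigma, 3-symbol words classified by variation
count, plus Voss pattern probabilities). Respiratory features are summary
statistics of per-breath instantaneous rate, median-indexed relative tidal
volume and I:E ratio from trough–peak–trough segmentation (minimum breath
duration 1.5 s, amplitude threshold 0.1x median prominence). Short or
degenerate inputs yield NaN (masked), never exceptions.

## Coupling features (the core block)

Both directions are computed for every directional method: linear Granger
causality (GC), kernel GC, large-scale nonlinear GC (lsNGC, F-statistic
and affinity), ML-based GC (small MLP and degree-2 polynomial ridge), and
transfer entropy (raw and normalized); plus the GC ratio and
directionality indices, binned joint/conditional entropies and mutual
information (lag 0 and max over ±1 s), cross-sample entropy, the extreme
lagged Pearson correlation and its lag (signed value of greatest
magnitude, ties toward lag 0), magnitude-squared coherence (band max and
HF mean) and a Hilbert phase-locking index.

**Sampling grid for the regression estimators.** A spline-interpolated
tachogram carries fresh innovation only at beat arrivals (~1.3 Hz). Fitted
far above that rate, nested autoregressive comparisons are dominated by
interpolation structure: the restricted model's residual is mostly
approximation bias, which *any* additional smooth regressor reduces — at
zero planted coupling the naive 25 Hz linear GC measured ~1.5 and
*decreased* with coupling strength. The regression-based estimators
(linear GC, kernel GC, lsNGC, ML-GC) therefore decimate the pair by a
further factor 10 to 2.5 Hz (Nyquist 1.25 Hz still covers the full
respiratory band). At that rate the zero-coupling GC is ~0.003, all
directional features rise strictly monotonically with planted coupling
(Spearman rho = 1.0 over four levels), and on one-way synthetic coupling
the forward GC exceeds the reverse in every recording. The
information-domain features remain at 25 Hz. The decimation factor and
selected orders are recorded in each recording's computation log.

**Estimator details.** Linear GC uses OLS with BIC order selection
(ceiling 5 at 2.5 Hz, i.e. a 2 s window) and 1/(n-k) residual-variance
normalization; near-collinear lag matrices fall back to the minimum-norm
solution with the effective rank in the denominator; negative
finite-sample estimates are clipped to 0 in the manifest output and logged
raw. Kernel GC uses a Nystroem RBF feature map (100 landmarks, median
pairwise-distance bandwidth times a width multiplier) with ridge
regression; as the width grows the map linearizes and the index approaches
linear GC. lsNGC clusters the source's 3-lag embedding with k-means
(k = 8), appends Gaussian RBF activations of the cluster distances to the
target autoregression, and reports the nested-model F-statistic
(numerator df = k) plus the affinity `1 - RSS_full/RSS_restricted`; with a
single center the activations are constant and the F-statistic is 0. Under
independence the F-statistic is calibrated against its F reference
distribution. ML-GC fits restricted and full predictors of identical
capacity: the restricted design includes a time-shuffled surrogate of the
source lags (same dimensionality and marginals, no temporal alignment),
which removes the systematic negative null bias that a plain nested
comparison shows for flexible learners; the value is
`ln(MSE_restricted/MSE_full)` on a held-out 30% tail. Transfer entropy
uses equal-frequency binning (4 bins; low-cardinality inputs map to their
values), lag 1 sample, and subtracts a 20-shuffle baseline, floored at 0;
the normalized variant divides by the target's conditional entropy.

## Modeling and evaluation

Datasets D1–D6 are nested feature sets: D1 demographic+cardiac, D2 +
respiratory, D3 + causal/information (all 157), D4 = D3 without
demographics (152), and D5/D6 the 35 features of D3/D4 ranked by pooled
|Shapley|. Evaluation is stratified 10-fold CV (stratification guarantees
all three classes in every test fold at this cohort size); inside each
fold the median imputer, SMOTE upsampler (default strategy 200/200/200,
k = 5 neighbors, reduced with a flag when a class is smaller) and
standardizer are fit on the training part only, so synthetic rows never
reach a test fold. The model zoo covers plain/ridge/lasso logistic
regression, decision tree, SVM, random forest, gradient boosting, naive
Bayes, k-NN, AdaBoost, XGBoost and an MLP; a small optional per-fold
random search over fixed grids is available (off by default — the pipeline
contracts are independent of tuning). Metrics are accuracy, macro
precision/recall/F1 (per-class from TP/FP/FN; the paper-style F1 form
2TP/(2TP+FN+FP) per class), multiclass MCC from predicted/true class
counts with a zero-denominator guard, and one-vs-rest macro AUC. The best
model per dataset is the one with highest mean CV accuracy. Datasets are
compared metric-by-metric with two-sided Wilcoxon signed-rank tests paired
by fold (alpha 0.05, no multiplicity correction); demographics are
compared across groups with Kruskal–Wallis tests.

## Explainability and feature selection

Shapley attributions use Monte-Carlo permutation sampling
(Strumbelj–Kononenko): for each explained sample, feature-order
permutations are drawn and features switch one at a time from a background
draw (up to 100 rows) to the explained value; marginal output changes
telescope, so local additivity against the sampled-background baseline is
exact. Permutation importance shuffles one column at a time (30 rounds)
and reports the mean ± SD increase of the one-vs-rest 1-AUC loss per
class. The reduced datasets take the top 35 features by mean |Shapley|
pooled over samples, folds and classes, with ties broken by name for
determinism.

## The coupling-only contrast experiment

To show that causal/information features add information beyond univariate
HRV, groups must differ *only* in coupling. Under the default AR(1)
mechanism this is impossible at the feature level: shifting variance
between a broadband intrinsic term and a narrowband respiratory term
reshapes the RR spectrum, which frequency-domain, fractal and symbolic
features all sense. The contrast cohort therefore uses the `pseudo_resp`
intrinsic mode, making the two variance components spectrally
interchangeable; only the alignment between the measured respiration and
the RR series varies with coupling. With coupling levels 0.2/0.45/0.7,
15 subjects per group and ridge logistic regression, D2 reaches ~0.67
mean CV accuracy while D3 reaches ~0.96 (paired one-sided Wilcoxon
p = 0.004). Residual D2 performance above chance traces to weak
envelope-modulation ("beating") signatures of summing two independent
narrowband processes.

## Problem sizes and numerical choices

Default recordings are 300 s at 250 Hz (the shortest admissible duration).
Generator-recovery checks use 500 recordings per group; the monotonicity
suite uses 50 recordings per coupling level at 4 levels; the contrast
experiment 45 subjects. Kernel/ML estimators cap training samples at 2000
(even stride); cross-sample entropy at 1500. RR intervals have a 250 ms
physiological floor. All randomness flows through seeded NumPy generators
(cohorts via `SeedSequence` spawning), and identical seeds reproduce
recordings, features and reports byte-for-byte.

## Known limitations

The generator's coupling is additive and linear in the respiration signal;
nonlinear estimators are validated on generic nonlinear test processes,
not on a nonlinear physiological mechanism. The symbolic-dynamics
quantization (6 bins over mu±2sigma) makes like-variation (2LV) dominance
unobtainable for smooth monotone series — classification into 2LV/2UV is
still exercised through alternation and mixed patterns. Real-data effects
(ectopy, artifacts, nonstationary breathing) are out of scope, as are
spectral/conditional multivariate GC variants.
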