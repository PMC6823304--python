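# Methods

This note records the modeling choices behind `tachyrisk`: the episode
definition and its edge cases, the window and feature conventions, the
cross-validation layout, the trajectory and lift construction, what the
synthetic generator does and does not emulate, and the numerical
decisions taken where the underlying method left room.

## Data model and preprocessing

A record is one subject's irregular multichannel time series over the
six numerics channels `hr` (beats/min), `rr` (breaths/min), `spo2` (%),
`abpsys`/`abpdias`/`abpmean` (mmHg).  Times are seconds from the
record's own start; absolute clock time plays no role anywhere in the
pipeline.  Channels may differ in coverage and sample times.  Records
nominally sampled at 1 Hz are decimated to the one-minute grid by
per-minute median before any downstream stage, so the entire pipeline
operates at a 1/60 Hz nominal period; the median is used rather than the
mean so single-sample artifacts within a minute do not leak into the
minute value.  How sub-minute and minute-level segments of one subject
should be reconciled is genuinely open; per-minute median decimation is
this package's choice.

## Episode detection

A tachycardia episode is operationally defined on the heart-rate channel:

* a sample is *suprathreshold* when HR ≥ 130 beats/min (the comparison
  is inclusive);
* consecutive suprathreshold samples separated by at most 30 min of
  threshold-free time belong to the same potential episode — a gap of
  exactly 30 min still merges, since only *more* than 30 min separates
  episodes;
* a potential episode is kept when its first-to-last suprathreshold span
  is at least 5 min *and* its duty cycle is at least 10%.

Episode boundaries are the first and last suprathreshold samples of the
merged cluster.  The duty-cycle denominator is the number of *available*
heart-rate samples inside the span, not elapsed minutes.  With complete
minute sampling the two coincide; under missing data the sample-count
denominator measures the density of tachycardia among the measurements
actually made, whereas an elapsed-time denominator would silently dilute
duty in records with gaps.  This is a deviation-risk point: on data with
long in-span gaps the two conventions can disagree about borderline
(≈10%) episodes.

The detector is validated against an exhaustive oracle that enumerates
maximal suprathreshold clusters by pairwise gap testing, on random
series up to 5,000 samples, and satisfies the expected monotonicities
(raising the threshold never adds suprathreshold samples; lowering the
duty floor never removes episodes) and idempotence (re-running on an
episode's span re-detects it).

## Windows and the three case/control designs

All analysis windows are 30 min long and half-open, `[t_start, t_end)`:
a case window ending at episode onset therefore never contains the onset
sample itself.  A lag-ℓ case window ends ℓ min before onset (lag-30
spans −60 to −30 min).  Group 1 anchors one window per episode; groups
2–3 use only each subject's earliest episode.  Windows with fewer than
20% of the expected heart-rate samples are dropped — the same 20% floor
used for interpolation, applied uniformly as the only stated coverage
number in the underlying method.

Controls for groups 1–2 are minute-aligned windows drawn uniformly from
subjects who never exhibit tachycardia, cycling over subjects until the
case count is matched; group-3 (internal) controls are drawn from the
same case subjects, from the stretch ending 3 h (`baseline_hours`)
before their first onset.  Control windows must pass an artifact screen:
every HR sample within [20, 300] beats/min and no single-step change
above 60 beats/min; failing draws are redrawn.  The screen is a stated
stand-in — the original artifact-exclusion rule for control windows is
unspecified — and its parameters are config-overridable.

## The 42 predictors

Six channel means, three SDs (hr/rr/spo2), six OLS slopes (per minute),
and, for hr/rr/spo2: total spectral power, autocorrelation sum,
approximate entropy, sample entropy, record density, and last-5/last-10
minute means and slopes.  Conventions:

* **Spectral power** (`fft_*`): the window is resampled to the uniform
  one-minute grid by cubic spline through the observed samples, with
  nearest-value extension for grid points outside the observed range (no
  extrapolation); the feature is the sum of squared amplitudes of the
  unnormalized DFT over all bins with frequency in the closed band
  [0, 1/120 Hz].  At minute sampling 1/120 Hz is the Nyquist frequency,
  so the whole one-sided spectrum contributes.  The DC bin is retained
  deliberately, which makes the feature strongly correlated with the
  channel mean — a documented property of the total-power definition,
  not an oversight.  Windows with under 20% of expected samples (or
  fewer than 4 samples, where a cubic spline is undefined) yield a
  missing value.
* **Autocorrelation sum** (`acs_*`): the sum of biased-estimator sample
  autocorrelations at lags 1–10 min on the interpolated grid.  The
  10-lag horizon is a package default (the feature's lag scheme is not
  specified in the underlying method) and is config-overridable.
  Zero-variance windows yield missing.
* **Entropies** (`aes_*`, `ses_*`): ApEn(m, r) with self-matches
  included and SampEn(m, r) = −log(A/B) with self-matches excluded,
  computed on the interpolated grid with the literature defaults m = 2,
  r = 0.2 × the series SD.  SampEn is undefined (missing) when no
  template pairs match; this happens routinely for 30-point windows of
  nearly white noise and is handled by the imputation stage.  Note ApEn
  is hump-shaped in r — it rises from small r, peaks, and only then
  decreases — so no global monotonicity in r should be expected; the
  tests assert monotone decrease only for r ≥ 1 SD.
* **Density** (`density_*`): observed/expected samples, clipped to
  [0, 1].
* Missing values are *never* imputed at featurization time; a feature
  that cannot be computed is an explicit missing entry, and imputation
  happens only inside each training fold.

All features are invariant to input row order and to time translation
of the whole window; ApEn/SampEn/FFT/autocorrelation are verified
against O(N²) brute-force oracles to 1e-10.

## Models

Two classifiers: lasso (L1) logistic regression and a random forest.
Cross-validation uses 10 folds, stratified by class and grouped by
subject (no subject contributes windows to both sides of a fold);
grouping is the defensible default for repeated-measures windows and can
be toggled off to stratify on windows alone.  Each fold's pipeline is
median imputation (training-fold medians only) → for the lasso,
standardization and an inner 5-fold search over the penalty weight
(10 candidate values, ROC-AUC criterion); for the forest, 500 trees,
√p features per split, no depth cap.  These hyperparameters are package
defaults; the underlying method states the algorithms but not their
settings.  Performance is the trapezoidal AUC over the pooled
out-of-fold ROC plus accuracy at the 0.5 threshold.  Feature rankings
average impurity importances (forest) or absolute standardized
coefficients (lasso) across folds, ties broken alphabetically.

The no-leakage contract is that the fold model scoring a window never
trained on it: with a pinned fold assignment, deleting a fold's test
window and retraining reproduces that fold's model bit-identically.
(Deleting a window necessarily changes *other* folds' models, since
every window is training data for the other nine folds.)

## Trajectories and lift

The instantaneous risk at minute t is the mean of the ten fold models'
probabilities for the window [t − 30 min, t); updating every minute
yields a trajectory over the whole record except its first 30 min, with
missing values where the window fails the coverage rule.  Scoring new
data with the fold-model mean is a package choice (the method does not
say which of the cross-validation models scores unseen minutes); it is
consistent with the pooled-scoring view of the ensemble.

The lift score divides a subject's risk over the 3 h before their first
episode by their own mean baseline risk.  The baseline segment is the
3 h ending exactly `baseline_hours` (default 3 h) before onset — the
same placement as the group-3 internal-control windows, chosen for
internal consistency; computing lift therefore requires 6 h of
episode-free data before onset, and subjects without it are excluded.
(Reading the baseline as the *same* 3-h pre-onset segment being scored
is a defensible alternative; it would force the mean lift over the
segment to 1 by construction and was rejected for that reason.)
Subjects whose baseline risk is below 1e-6 get missing lift rather than
an unstable ratio.  Group summaries are minute-aligned means with
normal-approximation 95% bands over subjects, missing minutes excluded
pairwise; the band construction is a package choice.

## The synthetic cohort generator

Each channel is a stationary AR(1) process around a typical stable-ICU
baseline (HR 85 ± 6, RR 18 ± 2.5, SpO2 97 ± 1, SBP 120 ± 8, DBP 65 ± 6,
MAP 83 ± 6; lag-1 autocorrelation 0.9).  Case subjects receive a linear
heart-rate ramp (default 0.35 beats/min per min) starting 90 min before
a scheduled onset, with respiratory rate rising and SpO2 falling in
proportion, followed by a duty-cycled burst in which an exact fraction
(default 0.7) of the episode's minutes exceed the threshold, the onset
minute always included.  Samples are deleted independently at the
missing rate (default 5%) and isolated single-sample artifact spikes
(HR 180–250) are injected at 0.2/h, spaced more than the merge gap from
each other and from the episode so they can never form or extend an
episode.  Outside episodes and artifacts the heart rate is clipped just
below the threshold, so control records are episode-free *by
construction* and ground truth is exact.  Records default to 12 h with
onset scheduled 50 min before the end, leaving more than the 6 h of
pre-onset data the lift computation needs.

This is a minimal statistical generator, not a physiological model: it
gives every feature family nontrivial values (variance → SDs, memory →
autocorrelation and entropy, ramps → slopes, deletions → density) with
controllable signal strength.  What it does not emulate: circadian and
treatment-driven nonstationarity, cross-channel causal structure beyond
the shared ramp, heteroscedastic monitor noise, block (rather than
independent) missingness, and the heavy-tailed artifact morphology of
real monitors.  Passing tests on this cohort therefore demonstrate the
pipeline's correctness and its ability to recover a planted pre-episode
signal — not clinical-grade performance on real ICU data, whose
published headline numbers require the archived clinical database and
are out of scope here.

## Problem sizes and tolerances

The test suite and acceptance script run desk-scale problems chosen as
the smallest sizes at which each property is statistically meaningful:
oracle equivalences on 200 random series (detector) and 50 series
(entropies) at 1e-10/1e-9 tolerances; model sanity on 100-window
separable and 2,000-window permuted-label cohorts (null AUC asserted
within 0.5 ± 0.05); the planted-drift cohort at its default 20 + 20
subjects; and the lift test pooling 20 simulation seeds (one-sided
t-test against 1 at α = 0.01).  Determinism is asserted at bit level:
identical seeds reproduce identical simulations, fold assignments and
scores.  Seeds fixed in tests were chosen as the conditions under which
the statistical assertions have comfortable margins, and every
randomized component is reproducible from a single integer seed.
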