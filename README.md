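# tachyrisk

Short-horizon prediction of tachycardia episodes from minute-level ICU
vital signs.

Tachycardia (sustained heart rate ≥ 130 beats/min) is an early,
non-specific marker of cardiorespiratory instability in critically ill
patients.  `tachyrisk` implements a complete pipeline for detecting
clinically meaningful tachycardia episodes in bedside-monitor "numerics"
data (heart rate, respiratory rate, SpO2 and arterial pressures sampled
roughly once a minute), building case/control analysis windows,
featurizing them, training cross-validated risk models, and turning
those models into minute-by-minute risk trajectories and patient-specific
lift scores.  It is aimed at critical-care data scientists working with
monitor trend data (e.g. the MIMIC numerics streams) who want a tested,
reproducible reference implementation — together with a built-in
synthetic cohort generator so every stage can be exercised and validated
without access to protected clinical data.

## The method

**Episode definition.** An episode is a cluster of heart-rate samples
with HR ≥ 130 beats/min in which consecutive suprathreshold samples are
separated by ≤ 30 min of threshold-free time, the first-to-last span
lasts ≥ 5 min, and the *duty cycle* — the fraction of HR samples inside
the span that are suprathreshold — is ≥ 10%.

**Windows and groups.** Case windows are the 30 min immediately before
episode onset (a lag-ℓ model uses the window ending ℓ min before
onset).  Three designs are supported: group 1 (every episode vs random
windows from never-tachycardic subjects, ≈1:1), group 2 (first episode
per subject vs the same controls) and group 3 (first episode vs
*internal* controls from the same subject's tachycardia-free baseline
3 h earlier).

**Features.** Each window yields 42 named predictors: channel means,
standard deviations, first-order regression slopes, total spectral power
over 0–1/120 Hz after cubic-spline gap filling (DC retained; requires
≥ 20% of expected samples), autocorrelation sums over lags 1–10 min,
approximate and sample entropy (m = 2, r = 0.2 × window SD), record
density, and last-5/last-10-min means and slopes.

**Models and trajectories.** L1-regularized logistic regression and a
random forest are trained with stratified, subject-grouped 10-fold
cross-validation; each window is scored out-of-fold and performance is
the pooled ROC AUC.  Scoring the trailing 30-min window at every minute
gives a risk trajectory r(t) ∈ [0, 1]; dividing r(t) over the 3 h before
a subject's first episode by that subject's mean baseline risk gives the
scale-free lift score.

## Worked example

```python
import numpy as np
import tachyrisk as tr

sim = tr.SimConfig(n_case_subjects=12, n_control_subjects=12, rng_seed=5)
records, truth = tr.simulate_cohort(sim)
cfg = tr.PipelineConfig(rng_seed=5)

episodes = [e for r in records for e in tr.detect_episodes(r, cfg)]
ep = episodes[0]
print(f"{len(episodes)} episodes; first: {ep.subject_id} "
      f"onset {ep.start_s/60:.0f} min, duration {ep.duration_s/60:.0f} min, "
      f"duty {ep.duty:.2f}")

X, y = tr.lagged_dataset(records, episodes, 0, cfg)
bundle = tr.crossval_train(X, y, "random_forest", cfg,
                           groups=X["subject"].to_numpy())
metrics, _ = tr.evaluate(bundle, y)
print(f"lag-0 random forest: AUC {metrics['auc']:.3f}, "
      f"accuracy {metrics['accuracy']:.3f} (n={metrics['n']})")
print("top 5 predictors:", ", ".join(tr.feature_ranking(bundle, 5)))

traj = tr.lift_trajectory(records[0], bundle, episodes, cfg)
last30 = traj.minutes >= traj.anchor_s / 60 - 30
print(f"{traj.subject_id}: baseline-relative lift over the last 30 min "
      f"before onset = {np.nanmean(traj.lift[last30]):.2f}")
```

prints

```
12 episodes; first: case_000 onset 670 min, duration 19 min, duty 0.67
lag-0 random forest: AUC 1.000, accuracy 1.000 (n=24)
top 5 predictors: fft_spo2, mean_hr, last_10min_mean_hr, last_5min_mean_hr, mean_spo2
case_000: baseline-relative lift over the last 30 min before onset = 10.10
```

The detector recovers the simulator's scheduled episode (onset minute
670, 20 scheduled minutes, 14/21 suprathreshold samples → duty 0.67);
the cross-validated forest separates pre-episode windows from control
windows perfectly because the planted heart-rate drift is strong
relative to the noise; heart-rate level features and spectral power
(which is dominated by the DC component, i.e. the mean) rank highest;
and the first case subject's risk in the final half hour is ten times
their own episode-free baseline.

The same pipeline is available from the shell via the `tachyrisk`
command (`simulate`, `detect`, `windows`, `featurize`, `train`,
`trajectory` subcommands; `tachyrisk --help` for details).

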