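"""Minute-by-minute risk trajectories, lagged models, and lift scores.

The instantaneous risk at minute ``t`` is the model's score for the
window covering the preceding 30 minutes of data; updating every minute
yields a trajectory over the whole record except its first 30 minutes.
"Lagged" models probe earlier horizons by shifting case windows back
``lag`` minutes before onset.  The lift score makes the trajectory
patient-relative: each subject's minute-by-minute risk over the 3 hours
before their first episode is divided by their own mean baseline risk,
taken over the 3-hour segment ending ``baseline_hours`` before onset.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import AnalysisWindow, case_windows, control_windows
from .config import PipelineConfig
from .episodes import Episode
from .features import featurize_windows, FEATURE_NAMES
from .models import ModelBundle
from .records import VitalRecord

log = logging.getLogger(__name__)


@dataclass
class RiskTrajectory:
    """Minute-indexed risk (and optionally lift) for one subject.

    ``minutes`` are minutes from record start; ``risk`` entries are in
    [0, 1] or NaN where the window failed the coverage rule.  ``anchor_s``
    is the first-episode onset time when known.
    """

    subject_id: str
    minutes: np.ndarray
    risk: np.ndarray
    lift: np.ndarray | None = None
    anchor_s: float | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"subject": self.subject_id, "minute": self.minutes,
                           "risk": self.risk})
        df["lift"] = self.lift if self.lift is not None else np.nan
        return df


def rolling_risk(record: VitalRecord, bundle: ModelBundle,
                 cfg: PipelineConfig, t_start_min: int | None = None,
                 t_end_min: int | None = None) -> RiskTrajectory:
    """Score the preceding-30-min window at every minute of the record.

    At each minute ``t`` (with ``t`` at least 30 minutes past the record
    start) the window ``[t-30 min, t)`` is featurized and scored by the
    mean of the bundle's fold models.  Minutes whose window has less than
    the minimum heart-rate coverage get NaN.  ``t_start_min``/``t_end_min``
    restrict the minute range (used by lift computation).
    """
    lo_s, hi_s = record.extent
    first = int(math.ceil(lo_s / 60.0 + cfg.window_min))
    last = int(math.floor(hi_s / 60.0))
    if t_start_min is not None:
        first = max(first, t_start_min)
    if t_end_min is not None:
        last = min(last, t_end_min)
    if last < first:
        return RiskTrajectory(record.subject_id, np.empty(0, dtype=int),
                              np.empty(0))

    minutes = np.arange(first, last + 1)
    windows = [AnalysisWindow(record.subject_id, 60.0 * (m - cfg.window_min),
                              60.0 * m, "trajectory", 0) for m in minutes]
    feats = featurize_windows({record.subject_id: record}, windows, cfg)
    risk = np.full(minutes.size, np.nan)
    density = feats["density_hr"].to_numpy()
    covered = ~np.isnan(density) & (density >= cfg.min_coverage)
    if covered.any():
        risk[covered] = bundle.predict(feats.loc[covered, list(FEATURE_NAMES)])
    return RiskTrajectory(record.subject_id, minutes, risk)


def lagged_dataset(records: dict[str, VitalRecord] | list[VitalRecord],
                   episodes: list[Episode], lag_min: float,
                   cfg: PipelineConfig, group: int = 1,
                   rng_seed: int | None = None
                   ) -> tuple[pd.DataFrame, np.ndarray]:
    """Feature table and labels for a lag-``lag_min`` model.

    Case windows are shifted back by the lag (cases whose shifted window
    exits the data are dropped and logged inside window construction);
    control windows are unchanged.  ``lag 0`` with ``group=1`` reproduces
    the group-1 dataset.  Returns ``(features, labels)`` where features
    carries the window metadata columns.
    """
    if isinstance(records, list):
        records = {r.subject_id: r for r in records}
    seed = cfg.rng_seed if rng_seed is None else rng_seed
    cases = case_windows(episodes, records, group, lag_min, cfg)
    controls = control_windows(records, episodes, group, cfg, seed,
                               n_target=len(cases))
    feats = featurize_windows(records, cases + controls, cfg)
    labels = np.array([1] * len(cases) + [0] * len(controls))
    return feats, labels


def compute_lift(minutes: np.ndarray, risk: np.ndarray, anchor_min: float,
                 cfg: PipelineConfig) -> np.ndarray | None:
    """Risk divided by the subject's own mean baseline risk.

    Baseline = mean risk over the 3-h segment ending ``baseline_hours``
    before the anchor (first-episode onset); lift is defined for the
    3 hours preceding the anchor and NaN elsewhere.  Returns None when
    the baseline is missing or below 1e-6 (lift undefined).
    """
    base_end = anchor_min - cfg.baseline_hours * 60.0
    base_start = base_end - 180.0
    in_base = (minutes >= base_start) & (minutes < base_end)
    base_risk = risk[in_base]
    base_risk = base_risk[~np.isnan(base_risk)]
    if base_risk.size == 0:
        return None
    baseline = float(base_risk.mean())
    if baseline < 1e-6:
        return None
    lift = np.full(minutes.size, np.nan)
    in_pre = (minutes >= anchor_min - 180.0) & (minutes <= anchor_min)
    lift[in_pre] = risk[in_pre] / baseline
    return lift


def lift_trajectory(record: VitalRecord, bundle: ModelBundle,
                    episodes: list[Episode],
                    cfg: PipelineConfig) -> RiskTrajectory | None:
    """Risk-and-lift trajectory for the 3 h before a subject's first episode.

    Requires enough tachycardia-free data before the first-episode onset
    to place both the 3-h baseline segment (ending ``baseline_hours``
    before onset) and the 3-h pre-onset segment; otherwise the subject is
    excluded (returns None, logged).  Lift is NaN everywhere when the
    baseline risk is below 1e-6.
    """
    own = [ep for ep in episodes if ep.subject_id == record.subject_id]
    if not own:
        log.info("subject %s has no episode; lift undefined", record.subject_id)
        return None
    anchor_s = min(ep.start_s for ep in own)
    anchor_min = anchor_s / 60.0
    need_start_min = anchor_min - cfg.baseline_hours * 60.0 - 180.0
    lo_s, _ = record.extent
    if need_start_min * 60.0 < lo_s - 1e-9:
        log.info("subject %s excluded from lift: under %.1f h of baseline "
                 "data before first onset", record.subject_id,
                 cfg.baseline_hours + 3.0)
        return None
    traj = rolling_risk(record, bundle, cfg,
                        t_start_min=int(math.ceil(need_start_min)),
                        t_end_min=int(math.floor(anchor_min)))
    lift = compute_lift(traj.minutes, traj.risk, anchor_min, cfg)
    if lift is None:
        log.info("subject %s: baseline risk missing or ~0; lift left missing",
                 record.subject_id)
        lift = np.full(traj.minutes.size, np.nan)
    return RiskTrajectory(record.subject_id, traj.minutes, traj.risk, lift,
                          anchor_s)


def aggregate_trajectories(trajectories: list[RiskTrajectory],
                           alignment: str = "to_onset",
                           value: str = "risk") -> pd.DataFrame:
    """Minute-aligned group mean, SD and normal 95% CI over subjects.

    ``alignment="to_onset"`` indexes minutes relative to each subject's
    anchor (onset at 0, negative = before); ``"to_window"`` uses absolute
    record minutes.  Missing minutes are excluded pairwise.
    """
    if len(trajectories) < 2:
        raise ValueError("need at least 2 trajectories to aggregate")
    if value not in ("risk", "lift"):
        raise ValueError("value must be 'risk' or 'lift'")
    series = []
    for traj in trajectories:
        vals = traj.risk if value == "risk" else traj.lift
        if vals is None:
            continue
        if alignment == "to_onset":
            if traj.anchor_s is None:
                raise ValueError(f"{traj.subject_id}: no anchor to align to")
            minutes = traj.minutes - traj.anchor_s / 60.0
        elif alignment == "to_window":
            minutes = traj.minutes.astype(float)
        else:
            raise ValueError(f"unknown alignment {alignment!r}")
        series.append(pd.Series(vals, index=np.round(minutes).astype(int)))
    wide = pd.concat(series, axis=1)
    mean = wide.mean(axis=1, skipna=True)
    sd = wide.std(axis=1, ddof=1)
    n = wide.notna().sum(axis=1)
    half = stats.norm.ppf(0.975) * sd / np.sqrt(n.clip(lower=1))
    return pd.DataFrame({"minute": wide.index, "mean": mean.values,
                         "sd": sd.values, "n": n.values,
                         "ci_lo": (mean - half).values,
                         "ci_hi": (mean + half).values})
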