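"""Pipeline configuration.

All clinically meaningful thresholds of the pipeline live here: the
tachycardia heart-rate threshold, the episode merge gap, minimum duration
and duty cycle, the analysis-window length, the internal-control baseline
offset, and the cross-validation layout.  Durations are expressed in the
units clinicians quote (minutes, hours) and converted to seconds
internally by the modules that consume them.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Thresholds and knobs shared across the pipeline.

    Parameters
    ----------
    tachy_threshold:
        Heart rate (beats/min) at or above which a sample counts as
        tachycardic.  130 beats/min is the "step change" threshold of the
        national early-warning schemas.
    merge_gap_min:
        Suprathreshold samples separated by at most this many minutes of
        threshold-free time belong to the same potential episode.
    min_duration_min:
        Minimum first-to-last suprathreshold span for a retained episode.
    min_duty:
        Minimum fraction of heart-rate samples inside the episode span
        that must be suprathreshold (the episode "density").
    window_min:
        Length of every analysis window, minutes.
    baseline_hours:
        Offset between the end of the internal-control baseline segment
        and the first episode onset (group 3).
    lag_min:
        Default lag between case-window end and episode onset.
    n_folds:
        Cross-validation folds.
    min_coverage:
        Fraction of expected samples a window (or an interpolated feature)
        needs before it is considered usable; also the spline-interpolation
        floor for spectral and lag-domain features.
    apen_m, apen_r_factor:
        Pattern length and tolerance factor (times window SD) for the
        approximate/sample entropy features.
    acf_max_lag:
        Largest lag (minutes) included in the autocorrelation-sum feature.
    artifact_hr_bounds, artifact_max_step:
        Artifact screen for control windows: admissible heart-rate range
        (beats/min) and largest admissible jump between consecutive
        samples.
    group_by_subject:
        Keep every subject's windows inside a single CV fold.  Toggle off
        to stratify on windows alone.
    """

    tachy_threshold: float = 130.0
    merge_gap_min: float = 30.0
    min_duration_min: float = 5.0
    min_duty: float = 0.10
    window_min: float = 30.0
    baseline_hours: float = 3.0
    lag_min: float = 0.0
    n_folds: int = 10
    rng_seed: int = 0
    min_coverage: float = 0.20
    apen_m: int = 2
    apen_r_factor: float = 0.2
    acf_max_lag: int = 10
    artifact_hr_bounds: tuple[float, float] = (20.0, 300.0)
    artifact_max_step: float = 60.0
    group_by_subject: bool = True
    rf_n_trees: int = 500
    lasso_inner_folds: int = 5
    nominal_period_s: float = 60.0

    def __post_init__(self) -> None:
        for name in ("merge_gap_min", "min_duration_min", "window_min",
                     "baseline_hours"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.min_duty <= 1:
            raise ValueError("min_duty must lie in (0, 1]")
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")
        if not 0 < self.min_coverage <= 1:
            raise ValueError("min_coverage must lie in (0, 1]")
        if self.lag_min < 0:
            raise ValueError("lag_min must be nonnegative")

    # -- seconds-valued views used throughout ------------------------------
    @property
    def merge_gap_s(self) -> float:
        return self.merge_gap_min * 60.0

    @property
    def min_duration_s(self) -> float:
        return self.min_duration_min * 60.0

    @property
    def window_s(self) -> float:
        return self.window_min * 60.0

    @property
    def baseline_s(self) -> float:
        return self.baseline_hours * 3600.0

    # -- serialization -----------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "artifact_hr_bounds" in raw:
            raw["artifact_hr_bounds"] = tuple(raw["artifact_hr_bounds"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["artifact_hr_bounds"] = list(data["artifact_hr_bounds"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
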