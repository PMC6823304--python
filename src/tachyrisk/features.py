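"""The 42 window predictors.

Each 30-min analysis window is summarized by 42 named features spanning
six channels:

* means of all six channels (``mean_*``);
* sample standard deviations of hr, rr, spo2 (``sd_*``);
* first-order regression slopes, per minute, of all six channels
  (``reg_*``);
* total spectral power in the 0–1/120 Hz band of hr, rr, spo2
  (``fft_*``), computed on a spline-interpolated one-minute grid with the
  DC component retained;
* autocorrelation sums over lags 1–10 min (``acs_*``);
* approximate and sample entropy (``aes_*``, ``ses_*``) with m = 2 and
  tolerance 0.2 × window SD;
* record density — fraction of expected samples present (``density_*``);
* short-horizon means and slopes over the last 5 and 10 minutes
  (``last_5min_*``, ``last_10min_*``) of hr, rr, spo2.

Features are missing-aware: a slot that cannot be computed (too few
samples, coverage below the 20% interpolation floor, zero variance where
variance is required) is NaN; imputation happens only at model-fitting
time.  Spectral, autocorrelation and entropy features are computed on a
uniform one-minute grid obtained by cubic-spline interpolation of the
available samples, with nearest-value extension at the window edges so
the spline never extrapolates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .config import PipelineConfig
from .cohort import AnalysisWindow
from .records import VitalRecord

_FULL_CHANNELS = ("hr", "rr", "spo2")
_ABP_CHANNELS = ("abpdias", "abpmean", "abpsys")

FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"mean_{c}" for c in ("abpdias", "abpmean", "abpsys", "hr", "rr", "spo2")]
    + [f"sd_{c}" for c in _FULL_CHANNELS]
    + [f"reg_{c}" for c in ("abpdias", "abpmean", "abpsys", "hr", "rr", "spo2")]
    + [f"fft_{c}" for c in _FULL_CHANNELS]
    + [f"acs_{c}" for c in _FULL_CHANNELS]
    + [f"aes_{c}" for c in _FULL_CHANNELS]
    + [f"ses_{c}" for c in _FULL_CHANNELS]
    + [f"density_{c}" for c in _FULL_CHANNELS]
    + [f"last_5min_mean_{c}" for c in _FULL_CHANNELS]
    + [f"last_5min_reg_{c}" for c in _FULL_CHANNELS]
    + [f"last_10min_mean_{c}" for c in _FULL_CHANNELS]
    + [f"last_10min_reg_{c}" for c in _FULL_CHANNELS]
)
assert len(FEATURE_NAMES) == 42

#: metadata columns carried alongside the 42 features in tabular form
WINDOW_META_COLUMNS = ["subject", "t_start_s", "t_end_s", "label", "group",
                       "lag_min", "episode_ref"]


# ---------------------------------------------------------------------------
# elementary features
# ---------------------------------------------------------------------------

def feat_mean_sd(values: np.ndarray) -> tuple[float, float]:
    """Arithmetic mean and (n-1) sample SD; NaN where undefined."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return math.nan, math.nan
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if values.size >= 2 else math.nan
    return mean, sd


def feat_slope(t_s: np.ndarray, values: np.ndarray) -> float:
    """OLS slope of value against time in minutes; NaN with <2 distinct times."""
    t_s = np.asarray(t_s, dtype=float)
    values = np.asarray(values, dtype=float)
    if t_s.size < 2 or np.ptp(t_s) == 0:
        return math.nan
    t_min = t_s / 60.0
    slope = np.polyfit(t_min, values, 1)[0]
    return float(slope)


def feat_density(n_observed: int, window_len_min: float,
                 nominal_period_s: float = 60.0) -> float:
    """Fraction of expected samples present, clipped to [0, 1]."""
    expected = window_len_min * 60.0 / nominal_period_s
    if expected <= 0:
        return math.nan
    return float(min(1.0, max(0.0, n_observed / expected)))


def feat_fft_power(grid_values: np.ndarray, period_s: float = 60.0,
                   f_max_hz: float = 1.0 / 120.0) -> float:
    """Total spectral power over [0, f_max] Hz of a uniform series.

    Sum of squared amplitudes of the unnormalized DFT over all frequency
    bins in the closed band — the DC component included, so the statistic
    correlates strongly with the channel mean by construction.  At the
    one-minute sampling period the 1/120 Hz upper edge is the Nyquist
    frequency, i.e. the whole one-sided spectrum contributes.
    """
    x = np.asarray(grid_values, dtype=float)
    if x.size < 4:
        return math.nan
    spectrum = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, d=period_s)
    band = freqs <= f_max_hz + 1e-12
    return float(np.sum(np.abs(spectrum[band]) ** 2))


def feat_autocorr(grid_values: np.ndarray, max_lag: int = 10) -> float:
    """Sum of sample autocorrelation coefficients at lags 1..max_lag.

    Uses the standard biased estimator r_k = c_k / c_0.  NaN when the
    series is too short (needs max_lag + 2 points) or has zero variance.
    """
    x = np.asarray(grid_values, dtype=float)
    n = x.size
    if n < max_lag + 2:
        return math.nan
    xc = x - x.mean()
    c0 = float(np.dot(xc, xc))
    if c0 == 0.0:
        return math.nan
    total = 0.0
    for k in range(1, max_lag + 1):
        total += float(np.dot(xc[:-k], xc[k:])) / c0
    return total


def _template_counts(x: np.ndarray, m: int, r: float, *, self_match: bool
                     ) -> np.ndarray | None:
    """Per-template counts of Chebyshev-matching length-m templates."""
    n = x.size
    n_templates = n - m + 1
    if n_templates < 1:
        return None
    # (n_templates, m) view of overlapping templates
    templates = np.lib.stride_tricks.sliding_window_view(x, m)
    dist = np.max(np.abs(templates[:, None, :] - templates[None, :, :]), axis=2)
    match = dist <= r
    if not self_match:
        np.fill_diagonal(match, False)
    return match.sum(axis=1)


def feat_apen(x: np.ndarray, m: int = 2, r: float | None = None,
              r_factor: float = 0.2) -> float:
    """Approximate entropy ApEn(m, r) with self-matches included.

    ``r`` defaults to ``r_factor`` times the series SD.  Returns NaN for
    series shorter than m + 2.
    """
    x = np.asarray(x, dtype=float)
    if x.size < m + 2:
        return math.nan
    if r is None:
        r = r_factor * float(np.std(x))

    def phi(mm: int) -> float:
        counts = _template_counts(x, mm, r, self_match=True)
        frac = counts / (x.size - mm + 1)
        return float(np.mean(np.log(frac)))

    return phi(m) - phi(m + 1)


def feat_sampen(x: np.ndarray, m: int = 2, r: float | None = None,
                r_factor: float = 0.2) -> float:
    """Sample entropy SampEn(m, r): −log(A/B), self-matches excluded.

    A and B count matching template pairs of length m+1 and m among the
    first N−m templates.  NaN when A or B is zero (undefined) or the
    series is too short.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < m + 2:
        return math.nan
    if r is None:
        r = r_factor * float(np.std(x))
    # restrict length-m templates to the first n-m so every template has a
    # length-(m+1) extension
    tm = np.lib.stride_tricks.sliding_window_view(x, m)[: n - m]
    tm1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)
    for arr, which in ((tm, "B"), (tm1, "A")):
        dist = np.max(np.abs(arr[:, None, :] - arr[None, :, :]), axis=2)
        match = dist <= r
        np.fill_diagonal(match, False)
        if which == "B":
            b = int(match.sum()) // 2
        else:
            a = int(match.sum()) // 2
    if a == 0 or b == 0:
        return math.nan
    return float(-math.log(a / b))


# ---------------------------------------------------------------------------
# interpolation to the minute grid
# ---------------------------------------------------------------------------

def interpolate_minute_grid(t_s: np.ndarray, values: np.ndarray,
                            t0: float, window_len_min: float,
                            min_coverage: float = 0.20,
                            nominal_period_s: float = 60.0
                            ) -> np.ndarray | None:
    """Resample window samples to the uniform one-minute grid.

    The grid has one point per nominal sample slot: ``t0 + k * 60`` for
    ``k = 0 .. window_len_min - 1``.  Interior gaps are filled by cubic
    spline through the observed samples; grid points before the first or
    after the last observation take the nearest observed value (no
    extrapolation).  Returns None when the available fraction is below
    ``min_coverage`` or fewer than 4 samples exist.
    """
    t_s = np.asarray(t_s, dtype=float)
    values = np.asarray(values, dtype=float)
    expected = int(round(window_len_min * 60.0 / nominal_period_s))
    if expected == 0 or t_s.size / expected < min_coverage or t_s.size < 4:
        return None
    grid = t0 + 60.0 * np.arange(expected)
    out = np.empty(expected)
    inside = (grid >= t_s[0]) & (grid <= t_s[-1])
    spline = CubicSpline(t_s, values)
    out[inside] = spline(grid[inside])
    out[grid < t_s[0]] = values[0]
    out[grid > t_s[-1]] = values[-1]
    return out


# ---------------------------------------------------------------------------
# window featurization
# ---------------------------------------------------------------------------

def featurize_window(record: VitalRecord, window: AnalysisWindow,
                     cfg: PipelineConfig) -> dict[str, float]:
    """Compute all 42 predictors for one analysis window.

    The window is the half-open interval ``[t_start_s, t_end_s)`` so a
    case window never contains the onset sample itself.  Channels absent
    from the record leave their slots NaN.  Deterministic and invariant to
    input row order and to time translation of the whole window.
    """
    t0, t1 = window.t_start_s, window.t_end_s
    wlen = (t1 - t0) / 60.0
    out = {name: math.nan for name in FEATURE_NAMES}

    for ch in _ABP_CHANNELS + _FULL_CHANNELS:
        if not record.has_channel(ch):
            continue
        t, v = record.in_window(ch, t0, t1)
        out[f"mean_{ch}"] = feat_mean_sd(v)[0]
        out[f"reg_{ch}"] = feat_slope(t, v)
        if ch not in _FULL_CHANNELS:
            continue

        out[f"sd_{ch}"] = feat_mean_sd(v)[1]
        out[f"density_{ch}"] = feat_density(v.size, wlen, cfg.nominal_period_s)

        for horizon in (5, 10):
            th, vh = record.in_window(ch, t1 - horizon * 60.0, t1)
            out[f"last_{horizon}min_mean_{ch}"] = feat_mean_sd(vh)[0]
            out[f"last_{horizon}min_reg_{ch}"] = feat_slope(th, vh)

        grid = (None if t.size == 0 else
                interpolate_minute_grid(t, v, t0, wlen, cfg.min_coverage,
                                        cfg.nominal_period_s))
        if grid is None:
            continue
        out[f"fft_{ch}"] = feat_fft_power(grid)
        out[f"acs_{ch}"] = feat_autocorr(grid, cfg.acf_max_lag)
        out[f"aes_{ch}"] = feat_apen(grid, cfg.apen_m, r_factor=cfg.apen_r_factor)
        out[f"ses_{ch}"] = feat_sampen(grid, cfg.apen_m, r_factor=cfg.apen_r_factor)
    return out


def featurize_windows(records: dict[str, VitalRecord] | list[VitalRecord],
                      windows: list[AnalysisWindow],
                      cfg: PipelineConfig) -> pd.DataFrame:
    """Feature table for many windows: metadata columns + 42 feature columns."""
    if isinstance(records, list):
        records = {r.subject_id: r for r in records}
    rows = []
    for w in windows:
        rec = records[w.subject_id]
        row = {"subject": w.subject_id, "t_start_s": w.t_start_s,
               "t_end_s": w.t_end_s, "label": w.label, "group": w.group,
               "lag_min": w.lag_min, "episode_ref": w.episode_ref}
        row.update(featurize_window(rec, w, cfg))
        rows.append(row)
    return pd.DataFrame(rows, columns=WINDOW_META_COLUMNS + list(FEATURE_NAMES))
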