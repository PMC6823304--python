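"""Vital-sign record model and CSV input/output.

A :class:`VitalRecord` holds one subject's irregular, multichannel
minute-level time series.  Channels are the six numerics streams used
throughout: heart rate (``hr``, beats/min), respiratory rate (``rr``,
breaths/min), pulse-oximetry saturation (``spo2``, %), and systolic /
diastolic / mean arterial pressure (``abpsys``, ``abpdias``, ``abpmean``,
mmHg).  Times are seconds from each record's own start; channels may have
different sample times and different coverage.

The canonical interchange format is a long CSV with columns
``subject,time_s,channel,value``; a wide per-minute matrix is accepted for
convenience.  Records nominally sampled at 1 Hz are decimated to the
one-minute grid by per-minute median before any downstream stage, so the
whole pipeline operates at 1/60 Hz.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

CHANNELS = ("hr", "rr", "spo2", "abpsys", "abpdias", "abpmean")

#: tolerated spellings for the six canonical channel names
CHANNEL_ALIASES = {
    "hr": "hr", "heart_rate": "hr", "heartrate": "hr", "pulse": "hr",
    "rr": "rr", "resp": "rr", "resp_rate": "rr", "respiratory_rate": "rr",
    "spo2": "spo2", "sao2": "spo2", "o2sat": "spo2",
    "abpsys": "abpsys", "abp_sys": "abpsys", "sbp": "abpsys",
    "abpdias": "abpdias", "abp_dias": "abpdias", "dbp": "abpdias",
    "abpmean": "abpmean", "abp_mean": "abpmean", "map": "abpmean",
}


@dataclass
class VitalRecord:
    """One subject's multichannel vital-sign time series.

    ``channels`` maps a canonical channel name to a pair of aligned float
    arrays ``(time_s, value)`` with strictly increasing times and finite
    values.  Absent samples are simply absent (no sentinel values).
    """

    subject_id: str
    channels: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    nominal_period_s: float = 60.0

    def __post_init__(self) -> None:
        clean: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for name, (t, v) in self.channels.items():
            if name not in CHANNELS:
                raise ValueError(f"unknown channel {name!r}")
            t = np.asarray(t, dtype=float)
            v = np.asarray(v, dtype=float)
            if t.shape != v.shape:
                raise ValueError(f"{name}: times and values differ in length")
            if t.size and np.any(np.diff(t) <= 0):
                raise ValueError(f"{name}: times must be strictly increasing")
            if np.any(~np.isfinite(v)):
                raise ValueError(f"{name}: values must be finite")
            if name == "spo2" and v.size and (v.min() < 0 or v.max() > 100):
                raise ValueError("spo2 values must lie in [0, 100]")
            if name in ("hr", "rr") and v.size and v.min() < 0:
                raise ValueError(f"{name} values must be nonnegative")
            clean[name] = (t, v)
        self.channels = clean

    # -- access helpers ----------------------------------------------------
    def channel(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(time_s, value)`` arrays for a channel (KeyError if absent)."""
        return self.channels[name]

    def has_channel(self, name: str) -> bool:
        return name in self.channels and self.channels[name][0].size > 0

    def in_window(self, name: str, t0: float, t1: float
                  ) -> tuple[np.ndarray, np.ndarray]:
        """Samples of ``name`` with ``t0 <= time_s < t1`` (empty if no channel)."""
        if name not in self.channels:
            return np.empty(0), np.empty(0)
        t, v = self.channels[name]
        lo, hi = np.searchsorted(t, [t0, t1], side="left")
        return t[lo:hi], v[lo:hi]

    @property
    def extent(self) -> tuple[float, float]:
        """(first, last) sample time over all channels; (0, 0) if empty."""
        starts = [t[0] for t, _ in self.channels.values() if t.size]
        ends = [t[-1] for t, _ in self.channels.values() if t.size]
        if not starts:
            return 0.0, 0.0
        return min(starts), max(ends)

    def to_minute_grid(self) -> "VitalRecord":
        """Decimate to a one-minute grid by per-minute median.

        Samples within minute ``k`` (times in ``[60k, 60(k+1))``) collapse
        to their median at time ``60k``.  Records already at the minute
        period are returned unchanged.
        """
        if self.nominal_period_s >= 60.0:
            return self
        channels = {}
        for name, (t, v) in self.channels.items():
            minute = np.floor(t / 60.0).astype(int)
            grouped = pd.Series(v).groupby(minute).median()
            channels[name] = (grouped.index.to_numpy(dtype=float) * 60.0,
                              grouped.to_numpy(dtype=float))
        return VitalRecord(self.subject_id, channels, nominal_period_s=60.0)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _normalize_channel(raw: str) -> str | None:
    key = str(raw).strip().lower()
    return CHANNEL_ALIASES.get(key)


def read_records(path: str | Path, format: str = "long_csv",
                 nominal_period_s: float = 60.0) -> list[VitalRecord]:
    """Read vital-sign records from CSV; one :class:`VitalRecord` per subject.

    Long format needs columns ``subject,time_s,channel,value``; wide format
    needs ``subject,time_s`` plus one column per channel with empty cells
    for missing samples.  Rows with non-finite values are dropped and
    counted in the log; unknown channel names trigger a warning and are
    skipped.  Records declared at a sub-minute nominal period are decimated
    to the minute grid.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - surface the parser's message
        raise ValueError(f"unparseable CSV {path}: {exc}") from exc

    if format == "long_csv":
        required = {"subject", "time_s", "channel", "value"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: long CSV lacks columns {sorted(missing)}")
        df = df.copy()
        df["channel"] = df["channel"].map(lambda c: _normalize_channel(c))
        n_unknown = int(df["channel"].isna().sum())
        if n_unknown:
            warnings.warn(f"{path}: skipped {n_unknown} rows with unknown channel",
                          stacklevel=2)
            df = df.dropna(subset=["channel"])
        df["value"] = pd.to_numeric(df["value"], errors="coerce")
        df["time_s"] = pd.to_numeric(df["time_s"], errors="coerce")
        bad = ~np.isfinite(df["value"]) | ~np.isfinite(df["time_s"])
        n_bad = int(bad.sum())
        if n_bad:
            log.info("%s: dropped %d rows with non-finite time or value",
                     path, n_bad)
            df = df[~bad]
        long = df
    elif format == "wide_csv":
        if not {"subject", "time_s"} <= set(df.columns):
            raise ValueError(f"{path}: wide CSV lacks subject/time_s columns")
        value_cols = [c for c in df.columns if c not in ("subject", "time_s")]
        keep, dropped = [], []
        for c in value_cols:
            (keep if _normalize_channel(c) else dropped).append(c)
        if dropped:
            warnings.warn(f"{path}: skipped unknown channel columns {dropped}",
                          stacklevel=2)
        long = df.melt(id_vars=["subject", "time_s"], value_vars=keep,
                       var_name="channel", value_name="value")
        long["channel"] = long["channel"].map(_normalize_channel)
        long["value"] = pd.to_numeric(long["value"], errors="coerce")
        long["time_s"] = pd.to_numeric(long["time_s"], errors="coerce")
        long = long[np.isfinite(long["value"]) & np.isfinite(long["time_s"])]
    else:
        raise ValueError(f"unknown format {format!r}")

    records = []
    for subject, sub in long.groupby("subject", sort=True):
        channels = {}
        for channel, rows in sub.groupby("channel"):
            rows = rows.sort_values("time_s").drop_duplicates("time_s")
            channels[channel] = (rows["time_s"].to_numpy(dtype=float),
                                 rows["value"].to_numpy(dtype=float))
        rec = VitalRecord(str(subject), channels,
                          nominal_period_s=nominal_period_s)
        records.append(rec.to_minute_grid())
    return records


def write_records(records: list[VitalRecord], path: str | Path) -> None:
    """Write records as the canonical long CSV."""
    rows = []
    for rec in records:
        for name, (t, v) in rec.channels.items():
            rows.append(pd.DataFrame({"subject": rec.subject_id, "time_s": t,
                                      "channel": name, "value": v}))
    if rows:
        out = pd.concat(rows, ignore_index=True)
    else:
        out = pd.DataFrame(columns=["subject", "time_s", "channel", "value"])
    write_table(out, path)


def write_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write any tabular pipeline product as CSV with a deterministic header.

    Floats are written at full (shortest round-trip) precision so that
    ``read_table(write_table(x)) == x``.
    """
    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame(rows)
    if rows.shape[1] == 0:
        raise ValueError("refusing to write a table with no columns")
    rows.to_csv(path, index=False, float_format="%.17g")


def read_table(path: str | Path) -> pd.DataFrame:
    """Inverse of :func:`write_table`."""
    return pd.read_csv(path, float_precision="round_trip")
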