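"""Operational tachycardia-episode detection.

A tachycardia episode is a cluster of heart-rate samples at or above the
tachycardia threshold (130 beats/min by default) in which consecutive
suprathreshold samples are separated by no more than the merge gap
(30 min) of threshold-free time, the first-to-last suprathreshold span
lasts at least the minimum duration (5 min), and at least the minimum
duty cycle (10%) of the heart-rate samples inside the span are
suprathreshold.

Conventions, stated once:

* threshold comparison is ``>=``;
* a gap of exactly the merge gap still merges ("more than 30 min of
  threshold-free time separates episodes");
* episode boundaries are the first and last suprathreshold samples of the
  merged cluster;
* the duty-cycle denominator is the number of *available* heart-rate
  samples inside the span, not elapsed minutes, so missing stretches do
  not silently dilute density.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .records import VitalRecord


@dataclass(frozen=True)
class Episode:
    """A detected tachycardia interval.

    ``start_s``/``end_s`` are the first and last suprathreshold sample
    times of the merged cluster; ``duty = n_supra / n_samples`` over the
    available heart-rate samples in ``[start_s, end_s]``.
    """

    subject_id: str
    start_s: float
    end_s: float
    n_samples: int
    n_supra: int

    @property
    def duty(self) -> float:
        return self.n_supra / self.n_samples

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def overlaps(self, t0: float, t1: float) -> bool:
        """True if [t0, t1] intersects [start_s, end_s]."""
        return t0 <= self.end_s and t1 >= self.start_s


def detect_episodes(record: VitalRecord, cfg: PipelineConfig) -> list[Episode]:
    """Detect tachycardia episodes in one record.

    Clusters consecutive suprathreshold heart-rate samples whose gaps are
    at most ``cfg.merge_gap_min`` minutes, then keeps clusters lasting at
    least ``cfg.min_duration_min`` minutes with duty cycle at least
    ``cfg.min_duty``.  Episodes are returned sorted by start time.

    Raises ``ValueError`` if the record has no heart-rate channel; an
    empty heart-rate series yields an empty list.
    """
    if "hr" not in record.channels:
        raise ValueError(f"record {record.subject_id!r} has no hr channel")
    t, v = record.channel("hr")
    if t.size == 0:
        return []

    supra = np.flatnonzero(v >= cfg.tachy_threshold)
    if supra.size == 0:
        return []

    # split where threshold-free time between consecutive supra samples
    # exceeds the merge gap
    gaps = np.diff(t[supra])
    breaks = np.flatnonzero(gaps > cfg.merge_gap_s)
    clusters = np.split(supra, breaks + 1)

    episodes = []
    for cluster in clusters:
        start, end = t[cluster[0]], t[cluster[-1]]
        if end - start < cfg.min_duration_s:
            continue
        lo = np.searchsorted(t, start, side="left")
        hi = np.searchsorted(t, end, side="right")
        n_samples = hi - lo
        n_supra = cluster.size
        if n_supra / n_samples < cfg.min_duty:
            continue
        episodes.append(Episode(record.subject_id, float(start), float(end),
                                int(n_samples), int(n_supra)))
    return episodes


def tachyfree_mask(record: VitalRecord, episodes: list[Episode],
                   guard_min: float, threshold: float = 130.0
                   ) -> list[tuple[float, float]]:
    """Intervals of the record far from tachycardia.

    Returns the maximal sub-intervals of the record extent that are at
    least ``guard_min`` minutes away from every episode and contain no
    suprathreshold heart-rate sample (isolated suprathreshold samples
    outside episodes split the intervals).  ``threshold`` should match the
    one used to detect ``episodes``.
    """
    lo, hi = record.extent
    if hi <= lo:
        return []
    guard_s = guard_min * 60.0
    intervals = [(lo, hi)]

    def subtract(iv: list[tuple[float, float]], a: float, b: float):
        out = []
        for x0, x1 in iv:
            if b <= x0 or a >= x1:
                out.append((x0, x1))
                continue
            if x0 < a:
                out.append((x0, a))
            if b < x1:
                out.append((b, x1))
        return out

    for ep in episodes:
        intervals = subtract(intervals, ep.start_s - guard_s, ep.end_s + guard_s)

    if record.has_channel("hr"):
        t, v = record.channel("hr")
        supra_times = t[v >= threshold]
        eps = 1e-9
        for ts in supra_times:
            intervals = subtract(intervals, ts - eps, ts + eps)

    return [(a, b) for a, b in intervals if b - a > 0]


# ---------------------------------------------------------------------------
# tabular round-trip
# ---------------------------------------------------------------------------

EPISODE_COLUMNS = ["subject", "start_s", "end_s", "duration_s",
                   "n_samples", "n_supra", "duty"]


def episodes_to_frame(episodes: list[Episode]) -> pd.DataFrame:
    rows = [{"subject": e.subject_id, "start_s": e.start_s, "end_s": e.end_s,
             "duration_s": e.duration_s, "n_samples": e.n_samples,
             "n_supra": e.n_supra, "duty": e.duty} for e in episodes]
    return pd.DataFrame(rows, columns=EPISODE_COLUMNS)


def frame_to_episodes(df: pd.DataFrame) -> list[Episode]:
    return [Episode(str(r.subject), float(r.start_s), float(r.end_s),
                    int(r.n_samples), int(r.n_supra))
            for r in df.itertuples(index=False)]
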