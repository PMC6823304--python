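"""Case and control window construction.

Three case/control designs are supported, mirroring the three modeling
groups:

* **group 1** — one case window per tachycardia episode; controls are
  random 30-min windows from subjects who never exhibit tachycardia,
  count-matched roughly 1:1 to the cases;
* **group 2** — one case window per case subject, anchored to that
  subject's earliest episode; controls as in group 1;
* **group 3** — case windows as in group 2, but controls are *internal*:
  windows from the same case subjects, drawn from the tachycardia-free
  stretch ending ``baseline_hours`` before their first episode onset.

Case windows end ``lag_min`` minutes before the anchoring episode onset
(a lag-30 window spans −60 to −30 min relative to onset).  Control
windows must overlap no episode and pass an artifact screen: every
heart-rate sample in [20, 300] beats/min and no single-step change above
60 beats/min; failing draws are redrawn.  Windows with fewer than 20% of
the expected heart-rate samples are dropped with a logged reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .episodes import Episode
from .records import VitalRecord

log = logging.getLogger(__name__)

_MAX_DRAWS_PER_SUBJECT = 50


@dataclass(frozen=True)
class AnalysisWindow:
    """A labeled 30-min case or control segment.

    ``lag_min`` is the gap between window end and the anchoring episode
    onset (0 for controls); ``episode_ref`` identifies the anchor episode
    as ``"<subject>:<k>"`` or is empty for controls.
    """

    subject_id: str
    t_start_s: float
    t_end_s: float
    label: str            # "case" | "control"
    group: int            # 1 | 2 | 3
    lag_min: float = 0.0
    episode_ref: str = ""


def _hr_coverage(record: VitalRecord, t0: float, t1: float,
                 cfg: PipelineConfig) -> float:
    t, _ = record.in_window("hr", t0, t1)
    expected = (t1 - t0) / cfg.nominal_period_s
    return t.size / expected if expected > 0 else 0.0


def window_is_clean(record: VitalRecord, t0: float, t1: float,
                    cfg: PipelineConfig) -> bool:
    """Artifact screen: hr within bounds, no step larger than the cap."""
    _, v = record.in_window("hr", t0, t1)
    if v.size == 0:
        return False
    lo, hi = cfg.artifact_hr_bounds
    if v.min() < lo or v.max() > hi:
        return False
    if v.size >= 2 and np.max(np.abs(np.diff(v))) > cfg.artifact_max_step:
        return False
    return True


def _anchor_episodes(episodes: list[Episode], group: int) -> list[Episode]:
    """Group 1: every episode; groups 2-3: earliest episode per subject."""
    if group == 1:
        return sorted(episodes, key=lambda e: (e.subject_id, e.start_s))
    first: dict[str, Episode] = {}
    for ep in episodes:
        cur = first.get(ep.subject_id)
        if cur is None or ep.start_s < cur.start_s:
            first[ep.subject_id] = ep
    return [first[s] for s in sorted(first)]


def case_windows(episodes: list[Episode],
                 records: dict[str, VitalRecord] | list[VitalRecord],
                 group: int, lag_min: float,
                 cfg: PipelineConfig) -> list[AnalysisWindow]:
    """Case windows ending ``lag_min`` minutes before episode onsets.

    Windows that would precede the record's data, or whose heart-rate
    coverage falls below ``cfg.min_coverage``, are dropped and logged.
    """
    if group not in (1, 2, 3):
        raise ValueError(f"group must be 1, 2 or 3, got {group}")
    if lag_min < 0:
        raise ValueError("lag_min must be nonnegative")
    if isinstance(records, list):
        records = {r.subject_id: r for r in records}

    # stable per-subject episode index for provenance
    index: dict[str, int] = {}
    ep_ids = {}
    for ep in sorted(episodes, key=lambda e: (e.subject_id, e.start_s)):
        k = index.get(ep.subject_id, 0)
        ep_ids[id(ep)] = f"{ep.subject_id}:{k}"
        index[ep.subject_id] = k + 1

    out = []
    for ep in _anchor_episodes(episodes, group):
        rec = records[ep.subject_id]
        t_end = ep.start_s - lag_min * 60.0
        t_start = t_end - cfg.window_s
        rec_start, _ = rec.extent
        if t_start < rec_start:
            log.info("case window for %s dropped: precedes record start",
                     ep_ids[id(ep)])
            continue
        if _hr_coverage(rec, t_start, t_end, cfg) < cfg.min_coverage:
            log.info("case window for %s dropped: hr coverage below %.0f%%",
                     ep_ids[id(ep)], 100 * cfg.min_coverage)
            continue
        out.append(AnalysisWindow(ep.subject_id, t_start, t_end, "case",
                                  group, lag_min, ep_ids[id(ep)]))
    return out


def _draw_window(rec: VitalRecord, lo_s: float, hi_end_s: float,
                 episodes: list[Episode], cfg: PipelineConfig,
                 rng: np.random.Generator) -> tuple[float, float] | None:
    """One random minute-aligned eligible window in [lo_s, hi_end_s]."""
    last_start = hi_end_s - cfg.window_s
    if last_start < lo_s:
        return None
    lo_minute = int(np.ceil(lo_s / 60.0))
    hi_minute = int(np.floor(last_start / 60.0))
    if hi_minute < lo_minute:
        return None
    for _ in range(_MAX_DRAWS_PER_SUBJECT):
        t0 = 60.0 * rng.integers(lo_minute, hi_minute + 1)
        t1 = t0 + cfg.window_s
        if any(ep.overlaps(t0, t1) for ep in episodes):
            continue
        if _hr_coverage(rec, t0, t1, cfg) < cfg.min_coverage:
            continue
        if not window_is_clean(rec, t0, t1, cfg):
            continue
        return t0, t1
    return None


def control_windows(records: dict[str, VitalRecord] | list[VitalRecord],
                    episodes: list[Episode], group: int,
                    cfg: PipelineConfig, rng_seed: int,
                    n_target: int | None = None) -> list[AnalysisWindow]:
    """Control windows for one modeling group.

    Groups 1–2: uniformly random windows from episode-free subjects, one
    per subject pass, cycling over subjects until ``n_target`` (the case
    count) is reached or no subject yields a new window.  Group 3: one
    window per case subject from the stretch ending ``baseline_hours``
    before that subject's first episode onset; subjects without enough
    tachycardia-free baseline are excluded and logged.  Reproducible under
    ``rng_seed``.
    """
    if isinstance(records, list):
        records = {r.subject_id: r for r in records}
    rng = np.random.default_rng(rng_seed)
    by_subject: dict[str, list[Episode]] = {}
    for ep in episodes:
        by_subject.setdefault(ep.subject_id, []).append(ep)

    out: list[AnalysisWindow] = []
    if group in (1, 2):
        eligible = sorted(s for s in records if s not in by_subject)
        if n_target is None:
            n_target = len(eligible)
        exhausted: set[str] = set()
        while len(out) < n_target and len(exhausted) < len(eligible):
            for subject in eligible:
                if len(out) >= n_target:
                    break
                if subject in exhausted:
                    continue
                rec = records[subject]
                lo, hi = rec.extent
                drawn = _draw_window(rec, lo, hi, [], cfg, rng)
                if drawn is None:
                    exhausted.add(subject)
                    log.info("control subject %s excluded: no eligible window",
                             subject)
                    continue
                out.append(AnalysisWindow(subject, drawn[0], drawn[1],
                                          "control", group))
    elif group == 3:
        for subject in sorted(by_subject):
            rec = records[subject]
            onset = min(ep.start_s for ep in by_subject[subject])
            hi_end = onset - cfg.baseline_s
            lo, _ = rec.extent
            drawn = _draw_window(rec, lo, hi_end, by_subject[subject], cfg, rng)
            if drawn is None:
                log.info("group-3 subject %s excluded: under %.1f h of "
                         "tachycardia-free baseline", subject, cfg.baseline_hours)
                continue
            out.append(AnalysisWindow(subject, drawn[0], drawn[1],
                                      "control", 3))
    else:
        raise ValueError(f"group must be 1, 2 or 3, got {group}")
    return out


# ---------------------------------------------------------------------------
# tabular round-trip
# ---------------------------------------------------------------------------

WINDOW_COLUMNS = ["subject", "t_start_s", "t_end_s", "label", "group",
                  "lag_min", "episode_ref"]


def windows_to_frame(windows: list[AnalysisWindow]) -> pd.DataFrame:
    rows = [{"subject": w.subject_id, "t_start_s": w.t_start_s,
             "t_end_s": w.t_end_s, "label": w.label, "group": w.group,
             "lag_min": w.lag_min, "episode_ref": w.episode_ref}
            for w in windows]
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


def frame_to_windows(df: pd.DataFrame) -> list[AnalysisWindow]:
    df = df.fillna({"episode_ref": ""})
    return [AnalysisWindow(str(r.subject), float(r.t_start_s),
                           float(r.t_end_s), str(r.label), int(r.group),
                           float(r.lag_min), str(r.episode_ref))
            for r in df.itertuples(index=False)]
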