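"""Synthetic minute-level vital-sign cohorts with ground-truth episodes.

The generator emulates the data regime the pipeline is built for:
per-minute multichannel records with serially correlated noise, missing
stretches, isolated artifact spikes, a pre-episode physiological drift
(heart rate ramps up while respiratory rate rises and SpO2 falls), and a
duty-cycled suprathreshold tachycardia burst.  Each channel is a
stationary AR(1) process around its baseline mean; cases additionally
receive a linear heart-rate ramp starting ``drift_lead_min`` minutes
before a scheduled onset and then an episode in which a fixed fraction
(``episode_duty``) of minutes exceed the tachycardia threshold.

This is deliberately a minimal statistical generator, not a
physiological cardiovascular model: it gives every feature family
nontrivial values (variance for SDs, memory for autocorrelation and
entropy, ramps for slopes, deletions for density) with exactly known
ground truth.  Outside episodes and artifacts the heart rate is clipped
just below the tachycardia threshold, so control records contain no
detectable episode by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import VitalRecord

#: baseline (mean, stationary SD) per channel — typical stable ICU numerics
_BASELINES = {
    "hr": (85.0, 6.0),
    "rr": (18.0, 2.5),
    "spo2": (97.0, 1.0),
    "abpsys": (120.0, 8.0),
    "abpdias": (65.0, 6.0),
    "abpmean": (83.0, 6.0),
}


@dataclass
class SimConfig:
    """Cohort-generator settings.

    ``drift_slope`` is the linear heart-rate rise (beats/min per minute)
    over the ``drift_lead_min`` minutes before onset; respiratory rate
    and SpO2 are coupled to the same ramp through ``rr_coupling`` and
    ``spo2_coupling`` (their per-minute change per beat/min of HR rise).
    ``episode_duty`` is the exact fraction of episode minutes forced
    above the threshold.  ``artifact_rate`` spikes/hour produces isolated
    single-sample HR excursions in [180, 250] beats/min, spaced widely
    enough never to form an episode on their own.
    """

    n_case_subjects: int = 20
    n_control_subjects: int = 20
    record_hours: float = 12.0
    channel_baselines: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_BASELINES))
    ar_coeff: float = 0.9
    drift_lead_min: float = 90.0
    drift_slope: float = 0.35
    rr_coupling: float = 0.12
    spo2_coupling: float = -0.08
    episode_duty: float = 0.7
    episode_len_min: float = 20.0
    onset_min: float | None = None      # None → auto near record end
    missing_rate: float = 0.05
    artifact_rate: float = 0.2
    tachy_threshold: float = 130.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("episode_duty", "missing_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 <= self.ar_coeff < 1:
            raise ValueError("ar_coeff must lie in [0, 1)")
        if self.drift_lead_min <= 30:
            raise ValueError("drift_lead_min must exceed the 30-min window")

    @property
    def n_minutes(self) -> int:
        return int(round(self.record_hours * 60.0))

    def scheduled_onset_min(self) -> int:
        """Scheduled episode onset: near the record end, leaving a tail."""
        if self.onset_min is not None:
            onset = int(round(self.onset_min))
        else:
            onset = self.n_minutes - int(round(self.episode_len_min)) - 30
        if onset + self.episode_len_min >= self.n_minutes:
            raise ValueError("episode extends beyond the record end")
        if onset - self.drift_lead_min < 0:
            raise ValueError("drift would begin before the record start")
        return onset


def _ar1(n: int, sd: float, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) noise with marginal SD ``sd``."""
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    e = np.empty(n)
    e[0] = rng.normal(0.0, sd)
    shocks = rng.normal(0.0, innov_sd, size=n - 1)
    for i in range(1, n):
        e[i] = phi * e[i - 1] + shocks[i - 1]
    return e


def simulate_subject(sim: SimConfig, is_case: bool, seed: int
                     ) -> tuple[VitalRecord, list[dict]]:
    """One synthetic subject; fully determined by ``seed``.

    Returns the record and a ground-truth list (one dict per scheduled
    episode with ``onset_s``, ``end_s``, ``n_supra``).  Controls are
    guaranteed episode-free: their heart rate is clipped below the
    threshold except isolated artifact spikes too far apart to merge.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2025]))
    n = sim.n_minutes
    t = 60.0 * np.arange(n)
    clip_hr = sim.tachy_threshold - 2.0

    channels: dict[str, np.ndarray] = {}
    for name, (mu, sd) in sim.channel_baselines.items():
        channels[name] = mu + _ar1(n, sd, sim.ar_coeff, rng)

    truth: list[dict] = []
    ep_lo = ep_hi = -1
    if is_case:
        onset = sim.scheduled_onset_min()
        lead = int(round(sim.drift_lead_min))
        ep_len = int(round(sim.episode_len_min))
        ramp_idx = np.arange(onset - lead, onset)
        ramp = sim.drift_slope * np.arange(1, lead + 1)
        channels["hr"][ramp_idx] += ramp
        channels["rr"][ramp_idx] += sim.rr_coupling * ramp
        channels["spo2"][ramp_idx] += sim.spo2_coupling * ramp

        # duty-cycled burst: exactly round(duty * len) suprathreshold
        # minutes, always including the onset minute
        k = max(1, int(round(sim.episode_duty * ep_len)))
        supra_local = rng.choice(ep_len, size=k, replace=False)
        if 0 not in supra_local:
            supra_local[0] = 0
        supra_idx = onset + np.unique(supra_local)
        ep_slice = np.arange(onset, onset + ep_len)
        channels["hr"][ep_slice] = np.minimum(channels["hr"][ep_slice],
                                              clip_hr) \
            .clip(min=100.0)  # elevated but subthreshold between bursts
        channels["hr"][supra_idx] = rng.uniform(sim.tachy_threshold + 2.0,
                                                165.0, size=supra_idx.size)
        ep_lo, ep_hi = onset, onset + ep_len - 1
        truth.append({"subject_id": None, "onset_s": 60.0 * onset,
                      "end_s": 60.0 * supra_idx.max(),
                      "n_supra": int(supra_idx.size)})

    # clip non-episode heart rate below threshold so detection ground
    # truth is exact
    outside = np.ones(n, dtype=bool)
    if ep_lo >= 0:
        outside[ep_lo:ep_hi + 1] = False
    channels["hr"][outside] = np.minimum(channels["hr"][outside], clip_hr)

    # isolated artifact spikes, >= 62 min apart and well away from episodes
    n_spikes = rng.poisson(sim.artifact_rate * sim.record_hours)
    placed: list[int] = []
    for _ in range(n_spikes):
        for _attempt in range(20):
            cand = int(rng.integers(0, n))
            if ep_lo >= 0 and ep_lo - 32 <= cand <= ep_hi + 32:
                continue
            if any(abs(cand - p) < 62 for p in placed):
                continue
            placed.append(cand)
            channels["hr"][cand] = rng.uniform(180.0, 250.0)
            break

    channels["spo2"] = np.clip(channels["spo2"], 0.0, 100.0)
    channels["rr"] = np.clip(channels["rr"], 0.0, None)
    channels["hr"] = np.clip(channels["hr"], 0.0, None)

    rec_channels = {}
    for name, vals in channels.items():
        keep = rng.random(n) >= sim.missing_rate
        rec_channels[name] = (t[keep], vals[keep])
    record = VitalRecord("", rec_channels)
    return record, truth


def simulate_cohort(sim: SimConfig) -> tuple[list[VitalRecord], pd.DataFrame]:
    """Independent subjects with per-subject seeds derived from ``rng_seed``.

    Case subjects are named ``case_000`` …, controls ``ctrl_000`` ….
    Returns the records (minute grid, long-CSV-compatible) and a truth
    table with one row per scheduled episode.
    """
    records: list[VitalRecord] = []
    truth_rows: list[dict] = []
    seeds = np.random.SeedSequence(sim.rng_seed).generate_state(
        sim.n_case_subjects + sim.n_control_subjects) % (2**31 - 1)
    idx = 0
    for i in range(sim.n_case_subjects):
        rec, truth = simulate_subject(sim, True, int(seeds[idx])); idx += 1
        rec.subject_id = f"case_{i:03d}"
        records.append(rec)
        for row in truth:
            row["subject_id"] = rec.subject_id
            truth_rows.append(row)
    for i in range(sim.n_control_subjects):
        rec, _ = simulate_subject(sim, False, int(seeds[idx])); idx += 1
        rec.subject_id = f"ctrl_{i:03d}"
        records.append(rec)
    truth = pd.DataFrame(truth_rows,
                         columns=["subject_id", "onset_s", "end_s", "n_supra"])
    return records, truth
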