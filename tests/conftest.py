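"""Shared fixtures: record builders and a small planted-drift cohort.

The heavier fixtures (simulated cohort, trained bundles) are
session-scoped so the model and trajectory tests share one training run.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import tachyrisk as tr

warnings.filterwarnings(
    "ignore", message=".*LogisticRegressionCV.*", category=FutureWarning)


def make_record(hr, subject="s1", start_min=0, extra_channels=None,
                period_min=1.0):
    """A VitalRecord with an hr series at a regular minute grid."""
    hr = np.asarray(hr, dtype=float)
    t = 60.0 * (start_min + period_min * np.arange(hr.size))
    channels = {"hr": (t, hr)}
    for name, vals in (extra_channels or {}).items():
        vals = np.asarray(vals, dtype=float)
        channels[name] = (t[: vals.size], vals)
    return tr.VitalRecord(subject, channels)


@pytest.fixture
def cfg():
    return tr.PipelineConfig()


@pytest.fixture(scope="session")
def drift_cohort():
    """Planted-drift cohort: 12 cases + 12 controls, fixed seed."""
    sim = tr.SimConfig(n_case_subjects=12, n_control_subjects=12, rng_seed=7)
    records, truth = tr.simulate_cohort(sim)
    cfg = tr.PipelineConfig(rng_seed=7)
    episodes = []
    for rec in records:
        episodes.extend(tr.detect_episodes(rec, cfg))
    return {"sim": sim, "records": records, "truth": truth,
            "episodes": episodes, "cfg": cfg}


@pytest.fixture(scope="session")
def drift_dataset(drift_cohort):
    X, y = tr.lagged_dataset(drift_cohort["records"],
                             drift_cohort["episodes"], 0,
                             drift_cohort["cfg"])
    return X, y


@pytest.fixture(scope="session")
def lasso_bundle(drift_cohort, drift_dataset):
    X, y = drift_dataset
    return tr.crossval_train(X, y, "lasso_logistic", drift_cohort["cfg"],
                             groups=X["subject"].to_numpy())
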