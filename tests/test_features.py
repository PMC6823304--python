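"""The 42 window predictors against brute-force oracles and invariants."""

import math

import numpy as np
import pandas as pd
import pytest

import tachyrisk as tr
from tachyrisk.cohort import AnalysisWindow
from tachyrisk.features import (FEATURE_NAMES, feat_apen, feat_autocorr,
                                feat_density, feat_fft_power, feat_mean_sd,
                                feat_sampen, feat_slope, featurize_window,
                                interpolate_minute_grid)

from conftest import make_record
from oracles import (apen_oracle, autocorr_sum_oracle, dft_power_oracle,
                     ols_slope_oracle, sampen_oracle)


class TestMeanSdSlope:
    def test_mean_and_sample_sd(self):
        assert feat_mean_sd([60, 70, 80]) == (70.0, 10.0)

    def test_constant_series_sd_zero(self):
        assert feat_mean_sd([5.0] * 10)[1] == 0.0

    def test_single_sample(self):
        mean, sd = feat_mean_sd([42.0])
        assert mean == 42.0 and math.isnan(sd)

    def test_unit_ramp_slope_per_minute(self):
        t = 60.0 * np.arange(30)
        assert feat_slope(t, 60.0 + t / 60.0) == pytest.approx(1.0)

    def test_constant_slope_zero(self):
        t = 60.0 * np.arange(10)
        assert feat_slope(t, np.full(10, 7.0)) == pytest.approx(0.0, abs=1e-12)

    def test_irregular_points_match_normal_equations(self):
        t = np.array([0.0, 130.0, 700.0])
        v = np.array([61.0, 64.5, 59.0])
        assert feat_slope(t, v) == pytest.approx(
            ols_slope_oracle(t / 60.0, v), abs=1e-10)

    def test_too_few_points_missing(self):
        assert math.isnan(feat_slope(np.array([0.0]), np.array([1.0])))


class TestSpectralPower:
    def test_all_zero_series(self):
        assert feat_fft_power(np.zeros(30)) == 0.0

    def test_constant_series_dc_only(self):
        x = np.full(30, 3.0)
        assert feat_fft_power(x) == pytest.approx(dft_power_oracle(x),
                                                  rel=1e-12)
        assert feat_fft_power(x) == pytest.approx((3.0 * 30) ** 2, rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_series_match_direct_dft(self, seed):
        x = np.random.default_rng(seed).normal(80, 5, size=30)
        assert feat_fft_power(x) == pytest.approx(dft_power_oracle(x),
                                                  rel=1e-12)

    def test_below_coverage_floor_missing(self):
        # 5 of 30 expected samples = 17% < 20% floor
        t = 60.0 * np.array([0, 7, 14, 21, 28], dtype=float)
        v = 80.0 + np.arange(5.0)
        assert interpolate_minute_grid(t, v, 0.0, 30.0) is None

    def test_interpolation_identity_when_gap_free(self):
        rng = np.random.default_rng(4)
        v = rng.normal(80, 5, size=30)
        t = 60.0 * np.arange(30)
        grid = interpolate_minute_grid(t, v, 0.0, 30.0)
        np.testing.assert_allclose(grid, v, atol=1e-9)

    def test_interpolation_never_extrapolates(self):
        # leading/trailing gaps take the nearest observed value
        t = 60.0 * np.arange(5, 25, dtype=float)
        v = np.linspace(70, 90, 20)
        grid = interpolate_minute_grid(t, v, 0.0, 30.0)
        assert np.all(grid[:5] == v[0]) and np.all(grid[25:] == v[-1])


class TestAutocorrelation:
    def test_constant_series_missing(self):
        assert math.isnan(feat_autocorr(np.full(30, 5.0)))

    @pytest.mark.parametrize("seed", range(4))
    def test_ar1_matches_lagged_product_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = np.empty(120)
        x[0] = rng.normal()
        for i in range(1, 120):
            x[i] = 0.8 * x[i - 1] + rng.normal()
        assert feat_autocorr(x, 10) == pytest.approx(
            autocorr_sum_oracle(x, 10), abs=1e-10)

    def test_white_noise_summary_near_zero(self):
        # Monte-Carlo: for iid noise each r_k has Bartlett SE 1/sqrt(N),
        # so the 10-lag sum has SE ~ sqrt(10/N)
        n = 4000
        x = np.random.default_rng(11).normal(size=n)
        assert abs(feat_autocorr(x, 10)) < 3 * math.sqrt(10 / n)

    def test_too_short_missing(self):
        assert math.isnan(feat_autocorr(np.arange(11.0), 10))


class TestEntropies:
    def test_constant_series_apen_zero(self):
        assert feat_apen(np.full(20, 3.0), m=2) == pytest.approx(0.0)

    def test_constant_series_sampen_zero(self):
        assert feat_sampen(np.full(20, 3.0), m=2) == pytest.approx(0.0)

    def test_alternating_series_matches_oracle(self):
        x = np.array([1.0, 2.0] * 6)
        r = 0.5
        assert feat_apen(x, 2, r=r) == pytest.approx(
            apen_oracle(x, 2, r), abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_series_match_template_count_oracles(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=int(rng.integers(10, 60)))
        r = 0.2 * float(np.std(x))
        assert feat_apen(x, 2, r=r) == pytest.approx(
            apen_oracle(x, 2, r), abs=1e-10)
        want = sampen_oracle(x, 2, r)
        got = feat_sampen(x, 2, r=r)
        if want is None:
            assert math.isnan(got)
        else:
            assert got == pytest.approx(want, abs=1e-10)

    @pytest.mark.parametrize("seed", range(6))
    def test_widening_tolerance_relaxes_apen_toward_zero(self, seed):
        # beyond the matching scale of the data (r >= 1 SD) ApEn decreases
        # monotonically in r and vanishes once r spans the whole range
        x = np.random.default_rng(100 + seed).normal(size=50)
        sd = float(np.std(x))
        a1, a2, a4 = (feat_apen(x, 2, r=c * sd) for c in (1.0, 2.0, 4.0))
        assert a1 >= a2 - 1e-12 >= a4 - 2e-12
        assert feat_apen(x, 2, r=2 * float(np.ptp(x))) == pytest.approx(0.0)

    def test_no_m_plus_1_matches_sampen_missing(self):
        # strictly widening increments: no two m+1 templates within r
        x = np.array([0.0, 1.0, 3.0, 7.0, 15.0, 31.0, 63.0])
        assert math.isnan(feat_sampen(x, 2, r=0.4))

    def test_too_short_missing(self):
        assert math.isnan(feat_apen(np.array([1.0, 2.0, 3.0]), m=2))


class TestDensity:
    @pytest.mark.parametrize("n, want", [(30, 1.0), (15, 0.5), (0, 0.0)])
    def test_fractions(self, n, want):
        assert feat_density(n, 30.0) == want

    def test_clipped_to_unit_interval(self):
        assert feat_density(40, 30.0) == 1.0


class TestFeaturizeWindow:
    def full_record(self, n=30, start_min=0, seed=0):
        # oscillation + weak noise: regular enough that the entropy
        # features are defined (as for serially correlated real vitals)
        rng = np.random.default_rng(seed)
        phase = 2 * np.pi * np.arange(n) / 10.0

        def chan(mean, amp):
            return mean + amp * np.sin(phase) + rng.normal(0, 0.1 * amp, n)

        extra = {c: chan(m, a) for c, (m, a) in
                 [("rr", (18, 2)), ("spo2", (97, 0.5)), ("abpsys", (120, 5)),
                  ("abpdias", (65, 4)), ("abpmean", (83, 4))]}
        return make_record(chan(85, 3), start_min=start_min,
                           extra_channels=extra)

    def test_full_window_populates_all_42(self, cfg):
        rec = self.full_record()
        w = AnalysisWindow("s1", 0.0, 1800.0, "case", 1)
        feats = featurize_window(rec, w, cfg)
        assert len(feats) == 42
        assert sorted(feats) == sorted(FEATURE_NAMES)
        missing = [k for k, v in feats.items() if math.isnan(v)]
        assert missing == []

    def test_absent_spo2_blanks_exactly_its_slots(self, cfg):
        rec = self.full_record()
        del rec.channels["spo2"]
        w = AnalysisWindow("s1", 0.0, 1800.0, "case", 1)
        feats = featurize_window(rec, w, cfg)
        missing = {k for k, v in feats.items() if math.isnan(v)}
        assert missing == {k for k in FEATURE_NAMES if k.endswith("spo2")}
        assert len(missing) == 12

    def test_time_translation_invariance(self, cfg):
        rec0 = self.full_record(seed=5)
        shift = 7200.0
        shifted = tr.VitalRecord("s1", {
            name: (t + shift, v) for name, (t, v) in rec0.channels.items()})
        f0 = featurize_window(rec0, AnalysisWindow("s1", 0.0, 1800.0, "c", 1),
                              cfg)
        f1 = featurize_window(shifted,
                              AnalysisWindow("s1", shift, shift + 1800.0,
                                             "c", 1), cfg)
        for k in FEATURE_NAMES:
            assert f0[k] == pytest.approx(f1[k], rel=1e-9, abs=1e-9,
                                          nan_ok=True), k

    def test_row_order_invariance_via_reader(self, cfg, tmp_path):
        rec = self.full_record(seed=8)
        rows = []
        for name, (t, v) in rec.channels.items():
            for ti, vi in zip(t, v):
                rows.append(("s1", ti, name, vi))
        rng = np.random.default_rng(0)
        shuffled = [rows[i] for i in rng.permutation(len(rows))]
        p = tmp_path / "r.csv"
        pd.DataFrame(shuffled, columns=["subject", "time_s", "channel",
                                        "value"]).to_csv(p, index=False)
        rec2 = tr.read_records(p)[0]
        w = AnalysisWindow("s1", 0.0, 1800.0, "case", 1)
        f0 = featurize_window(rec, w, cfg)
        f1 = featurize_window(rec2, w, cfg)
        for k in FEATURE_NAMES:
            assert f0[k] == pytest.approx(f1[k], rel=1e-12, nan_ok=True), k

    def test_short_horizon_equals_full_when_window_is_5min(self, cfg):
        rec = self.full_record(n=5)
        w = AnalysisWindow("s1", 0.0, 300.0, "case", 1)
        feats = featurize_window(rec, w, cfg)
        for ch in ("hr", "rr", "spo2"):
            assert feats[f"last_5min_mean_{ch}"] == feats[f"mean_{ch}"]
            assert feats[f"last_5min_reg_{ch}"] == feats[f"reg_{ch}"]

    def test_onset_sample_excluded_from_case_window(self, cfg):
        # window [0, 1800) must not see the sample at t=1800
        hr = np.full(31, 80.0)
        hr[30] = 150.0
        rec = make_record(hr)
        w = AnalysisWindow("s1", 0.0, 1800.0, "case", 1)
        feats = featurize_window(rec, w, cfg)
        assert feats["mean_hr"] == 80.0
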