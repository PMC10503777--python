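"""Feature extraction: beats, RC fits, outlier clamping, validity rules."""

import numpy as np
import pytest

from cvinfer.extract import (
    detect_beats,
    estimate_rc,
    extract_observables,
    replace_outliers,
    resample_and_filter,
    validate_segment,
)
from cvinfer.series import ObservableSeries, WaveformRecord
from cvinfer.waveforms import synthesize_waveforms


def _obs(t, pa=100.0, pv=5.0, hr=120.0, pp=40.0, rc=1.0):
    ones = np.ones_like(t)
    return ObservableSeries(t, pa * ones, pv * ones, hr * ones, pp * ones,
                            rc * ones)


class TestDetectBeats:
    def test_counts_on_synthetic_record(self, constant_obs):
        rec = synthesize_waveforms(constant_obs, seed=0)
        beats = detect_beats(rec.abp, rec.fs)
        assert abs(len(beats) - 120) <= 2
        assert np.all(np.diff(beats["onset"]) > 0)

    def test_flat_signal_yields_no_beats(self):
        assert len(detect_beats(np.full(1000, 80.0), 125.0)) == 0

    def test_tracks_rate_switch(self):
        t = np.arange(0.0, 60.0001, 0.1)
        hr = np.where(t < 30, 80.0, 160.0)
        obs = ObservableSeries(t, np.full_like(t, 100.0),
                               np.full_like(t, 5.0), hr,
                               np.full_like(t, 40.0), np.full_like(t, 1.0))
        rec = synthesize_waveforms(obs, seed=0)
        beats = detect_beats(rec.abp, rec.fs)
        early = beats[beats["onset"] < 25.0]["period"]
        late = beats[beats["onset"] > 35.0]["period"]
        assert 60.0 / early.mean() == pytest.approx(80.0, rel=0.05)
        assert 60.0 / late.mean() == pytest.approx(160.0, rel=0.05)

    def test_too_short_record_rejected(self):
        with pytest.raises(ValueError):
            detect_beats(np.zeros(100), 125.0)


class TestEstimateRC:
    def test_recovers_pure_exponential(self):
        dt = 1.0 / 125.0
        u = np.arange(60) * dt
        tau, r2 = estimate_rc(5.0 + 80.0 * np.exp(-u / 0.9), dt)
        assert tau == pytest.approx(0.9, abs=0.01)
        assert r2 > 0.99

    def test_scale_equivariance(self):
        dt = 1.0 / 125.0
        u = np.arange(60) * dt
        tau1, _ = estimate_rc(np.exp(-u / 0.6), dt)
        tau2, _ = estimate_rc(np.exp(-u / 1.2), dt)
        assert tau2 == pytest.approx(2.0 * tau1, rel=1e-6)

    def test_non_decaying_runoff_rejected(self):
        dt = 1.0 / 125.0
        rising = np.linspace(50.0, 90.0, 40)
        tau, _ = estimate_rc(rising, dt)
        assert np.isnan(tau)

    def test_too_few_samples(self):
        tau, _ = estimate_rc(np.array([90.0, 88.0]), 1.0 / 125.0)
        assert np.isnan(tau)


class TestReplaceOutliers:
    def test_constant_series_unchanged(self):
        x = np.full(500, 42.0)
        assert np.array_equal(replace_outliers(x), x)

    def test_spike_clamped_not_removed(self):
        rng = np.random.default_rng(0)
        x = rng.normal(100.0, 1.0, 1000)
        x[500] += 30.0  # far beyond 3 scaled MADs
        y = replace_outliers(x, window=200)
        assert y[500] < x[500]
        assert y[500] > 100.0  # clamped to the upper threshold, not deleted
        assert y.size == x.size

    def test_mad_floor_handles_degenerate_window(self):
        x = np.full(400, 10.0)
        x[200] = 30.0
        y = replace_outliers(x, window=100, eps=0.5)
        # MAD is 0; the epsilon floor keeps the threshold finite and the
        # spike is clamped to median + 3*eps
        assert y[200] == pytest.approx(10.0 + 3 * 0.5)
        assert np.all(y[:190] == 10.0)

    def test_idempotent_within_tolerance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.0, 1.0, 2000)
        x[::97] += 8.0
        once = replace_outliers(x)
        twice = replace_outliers(once)
        assert np.max(np.abs(twice - once)) < 0.15


class TestValidity:
    def test_valid_segment(self):
        t = np.arange(0.0, 300.0, 0.1)
        win = validate_segment(_obs(t))
        assert win.valid and win.reason is None

    @pytest.mark.parametrize("channel,value,reason", [
        ("pp", 8.0, "pulse pressure"),
        ("pv", 30.0, "venous pressure"),
        ("pa", 260.0, "arterial pressure"),
        ("hr", 20.0, "heart rate"),
        ("rc", -0.5, "rc"),
    ])
    def test_single_violation_reported(self, channel, value, reason):
        t = np.arange(0.0, 300.0, 0.1)
        obs = _obs(t)
        getattr(obs, channel)[1500] = value
        win = validate_segment(obs)
        assert not win.valid
        assert win.reason == reason


class TestResample:
    def test_identity_on_grid_aligned_input(self):
        grid = np.arange(0.0, 30.0, 0.1)
        chans = {c: (grid, np.linspace(10, 20, grid.size))
                 for c in ("pa", "pv", "hr", "pp", "rc")}
        out = resample_and_filter(chans, grid)
        assert np.allclose(out.pa, chans["pa"][1])

    def test_slow_sinusoid_survives_default_filter(self):
        grid = np.arange(0.0, 200.0, 0.1)
        wave = 100.0 + 5.0 * np.sin(2 * np.pi * 0.01 * grid)
        chans = {c: (grid, wave) for c in ("pa", "pv", "hr", "pp", "rc")}
        out = resample_and_filter(chans, grid)
        assert np.allclose(out.pa, wave)

    def test_missing_channel_rejected(self):
        grid = np.arange(0.0, 10.0, 0.1)
        with pytest.raises(ValueError):
            resample_and_filter({"pa": (grid, grid)}, grid)


class TestEndToEnd:
    def test_round_trip_within_tolerances(self, constant_obs):
        rec = synthesize_waveforms(constant_obs, seed=0)
        ext = extract_observables(rec)
        mid = (ext.t > 15) & (ext.t < 45)
        for c, true, tol in [("pa", 100.0, 0.02), ("pv", 5.0, 0.02),
                             ("hr", 120.0, 0.02), ("pp", 40.0, 0.05),
                             ("rc", 1.0, 0.15)]:
            vals = getattr(ext, c)[mid]
            assert np.max(np.abs(vals - true)) / true < tol, c

    def test_time_offset_invariance(self, constant_obs):
        rec = synthesize_waveforms(constant_obs, seed=0)
        shifted = WaveformRecord(rec.t + 1000.0, rec.abp.copy(),
                                 rec.cvp.copy(), rec.fs)
        a = extract_observables(rec)
        b = extract_observables(shifted)
        n = min(len(a), len(b))
        for c in ("pa", "pv", "hr", "pp", "rc"):
            assert np.allclose(getattr(a, c)[5:n - 5],
                               getattr(b, c)[5:n - 5], rtol=1e-6)

    def test_heart_rate_integral_matches_beat_count(self, constant_obs):
        rec = synthesize_waveforms(constant_obs, seed=0)
        beats = detect_beats(rec.abp, rec.fs)
        ext = extract_observables(rec)
        span = beats["onset"].iloc[-1] + beats["period"].iloc[-1] - \
            beats["onset"].iloc[0]
        sel = (ext.t >= beats["onset"].iloc[0]) & (
            ext.t <= beats["onset"].iloc[0] + span)
        integral = np.trapezoid(ext.hr[sel] / 60.0, ext.t[sel])
        assert abs(integral - len(beats)) <= 1.5

    def test_artifact_clamping_reduces_error(self, constant_obs):
        from cvinfer.waveforms import ArtifactConfig, inject_artifacts
        rec = synthesize_waveforms(constant_obs, seed=0)
        noisy = inject_artifacts(
            rec, ArtifactConfig(spike_rate=0.5, spike_amp=80.0), seed=5)
        clamped = extract_observables(noisy)
        raw = extract_observables(noisy, outlier_k=1e9)  # clamp disabled
        mid = (clamped.t > 15) & (clamped.t < 45)
        err_clamped = np.max(np.abs(clamped.pp[mid] - 40.0))
        err_raw = np.max(np.abs(raw.pp[mid] - 40.0))
        assert err_clamped <= err_raw

    def test_non_finite_venous_channel_rejected(self, constant_obs):
        rec = synthesize_waveforms(constant_obs, seed=0)
        rec.cvp[10] = np.nan
        with pytest.raises(ValueError, match="venous"):
            extract_observables(rec)

    def test_short_record_rejected(self, constant_obs):
        rec = synthesize_waveforms(constant_obs, seed=0)
        short = WaveformRecord(rec.t[:500], rec.abp[:500], rec.cvp[:500],
                               rec.fs)
        with pytest.raises(ValueError):
            extract_observables(short)
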