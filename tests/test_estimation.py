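"""Segmentation, the multi-start estimator and the Model/Results surface."""

import numpy as np
import pandas as pd
import pytest

import cvinfer as cv
from cvinfer.cost import CostConfig
from cvinfer.estimation import (
    estimate_segment,
    reconstruct_observables,
    segment_series,
    shock_indices,
    smooth_trace,
)
from cvinfer.params import PARAM_NAMES
from cvinfer.series import ObservableSeries

IDX = {n: i for i, n in enumerate(PARAM_NAMES)}


def _flat_obs(duration, dt=0.1, **kw):
    t = np.arange(0.0, duration + dt / 2, dt)
    vals = dict(pa=100.0, pv=5.0, hr=120.0, pp=40.0, rc=1.0)
    vals.update(kw)
    ones = np.ones_like(t)
    return ObservableSeries(t, vals["pa"] * ones, vals["pv"] * ones,
                            vals["hr"] * ones, vals["pp"] * ones,
                            vals["rc"] * ones)


class TestSegmentation:
    def test_25_minute_record_yields_12_windows(self):
        windows = segment_series(_flat_obs(1500.0))
        assert len(windows) == 12
        assert [w.start for w in windows] == [100.0 * k for k in range(12)]

    def test_single_window_record(self):
        assert len(segment_series(_flat_obs(300.0))) == 1

    def test_short_record_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="shorter"):
            assert segment_series(_flat_obs(299.0)) == []

    def test_invalid_windows_flagged_not_dropped(self):
        obs = _flat_obs(700.0)
        obs.pp[4500] = 5.0  # pulse pressure dips below 10 mmHg at t=450
        windows = segment_series(obs)
        # the dip at t=450 falls inside windows [200,500) and [300,600) only
        assert [w.valid for w in windows] == [True, True, False, False]
        assert all(w.reason == "pulse pressure"
                   for w in windows if not w.valid)


@pytest.fixture(scope="module")
def setup(control_trace, neonate_meta):
    obs = control_trace.observables()
    model = cv.ShockStateModel(obs, neonate_meta)
    seg = model.segment_data(model.windows[5])
    return model, seg


@pytest.fixture(scope="module")
def fitted(control_trace, neonate_meta):
    obs = control_trace.observables().window(120.0, 600.0 + 0.15)
    model = cv.ShockStateModel(obs, neonate_meta,
                               config=CostConfig(stride=300.0))
    return model.fit(n_starts=2, seed=3, maxiter=150)


class TestEstimateSegment:
    def test_deterministic_given_seed(self, setup):
        model, seg = setup
        cfg = model.config
        e1 = estimate_segment(seg, model.initial_bounds, cfg, n_starts=2,
                              rng=np.random.default_rng(7), maxiter=50)
        e2 = estimate_segment(seg, model.initial_bounds, cfg, n_starts=2,
                              rng=np.random.default_rng(7), maxiter=50)
        assert np.array_equal(e1.theta, e2.theta)
        assert e1.cost == e2.cost

    def test_more_restarts_never_worse(self, setup):
        """min over a superset of polished starts cannot increase J."""
        model, seg = setup
        cfg = model.config
        costs = {}
        for n in (1, 3):
            e = estimate_segment(seg, model.initial_bounds, cfg, n_starts=n,
                                 rng=np.random.default_rng(3), maxiter=100)
            costs[n] = e.cost
        # same rng stream: the 3-start pool contains strictly more polish
        # candidates drawn from a larger screen; allow equality
        assert costs[3] <= costs[1] * (1 + 1e-9) or costs[3] < 1e-8

    def test_estimate_respects_bounds(self, setup):
        model, seg = setup
        e = estimate_segment(seg, model.initial_bounds, model.config,
                             n_starts=2, rng=np.random.default_rng(0),
                             maxiter=100)
        assert model.initial_bounds.contains(e.theta)

    def test_rejects_zero_starts(self, setup):
        model, seg = setup
        with pytest.raises(ValueError):
            estimate_segment(seg, model.initial_bounds, model.config,
                             n_starts=0)


class TestSmoothingAndIndices:
    def test_single_row_smoothing_is_identity(self):
        df = pd.DataFrame([{**{n: float(i) for i, n in enumerate(PARAM_NAMES)},
                            "start": 0.0, "cost": 1.0, "winner": 0}])
        sm = smooth_trace(df, window=5)
        for n in PARAM_NAMES:
            assert sm[n].iloc[0] == df[n].iloc[0]

    def test_moving_average_matches_pandas(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({n: rng.normal(size=10) for n in PARAM_NAMES})
        df["start"] = np.arange(10) * 100.0
        sm = smooth_trace(df, window=3)
        expected = df["p_set"].rolling(3, center=True, min_periods=1).mean()
        assert np.allclose(sm["p_set"], expected)

    def test_index_arithmetic(self):
        df = pd.DataFrame([{**{n: 1.0 for n in PARAM_NAMES}, "start": 0.0}])
        df["iex_rel"] = -0.05
        df["dvv0_rel"] = 144.0
        df["m_const"] = -0.3
        df["m_slope"] = 0.0
        idx = shock_indices(df)
        assert idx["i_bar_ex"].iloc[0] == pytest.approx(-0.05 / 144.0 * 60.0)
        assert idx["m_svr_mid"].iloc[0] == pytest.approx(-0.3)

    def test_zero_current_zero_index(self):
        df = pd.DataFrame([{**{n: 1.0 for n in PARAM_NAMES}, "start": 0.0}])
        df["iex_rel"] = 0.0
        assert shock_indices(df)["i_bar_ex"].iloc[0] == 0.0


class TestReconstruction:
    def test_perfect_at_truth_on_varying_data(self, hypovolemic_trace,
                                              neonate_meta):
        obs = hypovolemic_trace.observables().window(120.0, 900.0)
        model = cv.ShockStateModel(obs, neonate_meta)
        seg = model.segment_data(model.windows[2])
        scen = hypovolemic_trace.scenario
        theta = cv.SIMULATION_REFERENCE.to_scaled().as_array()
        rec = reconstruct_observables(theta, seg)
        for c in ("hr", "rc", "pp"):
            assert rec["correlations"][c] > 0.999999

    def test_constant_channel_flagged(self, control_trace, neonate_meta):
        obs = control_trace.observables()
        obs.rc[:] = 0.5
        model = cv.ShockStateModel(obs, neonate_meta)
        seg = model.segment_data(model.windows[0])
        theta = cv.SIMULATION_REFERENCE.to_scaled().as_array()
        rec = reconstruct_observables(theta, seg)
        assert np.isnan(rec["correlations"]["rc"])
        assert rec["degenerate"]["rc"]

    def test_shuffled_reconstruction_uncorrelated(self, hypovolemic_trace,
                                                  neonate_meta):
        obs = hypovolemic_trace.observables().window(120.0, 900.0)
        model = cv.ShockStateModel(obs, neonate_meta)
        seg = model.segment_data(model.windows[2])
        theta = cv.SIMULATION_REFERENCE.to_scaled().as_array()
        rec = reconstruct_observables(theta, seg)
        rng = np.random.default_rng(0)
        shuffled = rng.permutation(rec["hr_bar"])
        r = np.corrcoef(shuffled, seg.hr)[0, 1]
        assert abs(r) < 0.1


class TestModelResults:
    def test_fit_deterministic(self, control_trace, neonate_meta):
        obs = control_trace.observables().window(120.0, 400.0)
        model = cv.ShockStateModel(obs, neonate_meta)
        r1 = model.fit(n_starts=2, seed=5, maxiter=100)
        r2 = model.fit(n_starts=2, seed=5, maxiter=100)
        pd.testing.assert_frame_equal(r1.estimates, r2.estimates)

    def test_estimates_schema_and_bounds(self, fitted):
        df = fitted.estimates
        assert list(df.columns) == ["start", *PARAM_NAMES, "cost", "winner"]
        for _, row in df.iterrows():
            theta = row[list(PARAM_NAMES)].to_numpy(dtype=float)
            assert fitted.final_bounds.contains(theta)

    def test_summary_mentions_indices(self, fitted):
        text = fitted.summary()
        assert "I_ex" in text and "M_SVR" in text and "K_max" in text

    def test_no_valid_segment_warns(self, neonate_meta):
        obs = _flat_obs(400.0, pp=5.0)  # invalid: pulse pressure too low
        model = cv.ShockStateModel(obs, neonate_meta)
        with pytest.warns(UserWarning, match="no valid segments"):
            res = model.fit(n_starts=1, seed=0, maxiter=10)
        assert res.n_segments == 0
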