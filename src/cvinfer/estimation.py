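"""Segment-wise inverse estimation of the hidden parameters.

The public surface follows the Model/Results convention: build a
:class:`ShockStateModel` from an observable series plus patient metadata,
call :meth:`~ShockStateModel.fit`, and read estimates, shock indices and
diagnostics off the returned :class:`ShockStateResults`.

Each valid 300-s window is fitted independently by multi-start
box-constrained minimization of the segment objective; a memory penalty
couples slowly-varying parameters across windows.  Derived shock indices:
the volume-loss rate Ī_ex = Ĩ_ex/ΔṼ_v0 (1/min), the non-autonomic
resistance modulation M_SVR at the segment midpoint, and the maximal
relative contractility K̃_max (mmHg).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import extract
from .bounds import ParameterBounds, build_bounds, update_bounds_from_observables
from .cost import (
    CostConfig,
    SegmentData,
    derivative_channels,
    model_channels,
    segment_objective,
    segment_objective_grad,
)
from .params import PARAM_NAMES, ModelParameters, PatientMeta
from .series import ObservableSeries, SegmentWindow, WaveformRecord

_IDX = {n: i for i, n in enumerate(PARAM_NAMES)}


def segment_series(obs: ObservableSeries, length: float = 300.0,
                   stride: float = 100.0) -> list[SegmentWindow]:
    """Overlapping analysis windows: starts at 0, stride, 2·stride, …

    A window whose end would coincide with the end of the record is kept
    only when it is the sole window (so a 300-s record yields one window,
    while a 25-min / 1500-s record yields 12, with starts 0 … 1100 s).
    Each window carries the validity verdict of
    :func:`cvinfer.extract.validate_segment`.
    """
    span = obs.duration if len(obs) else 0.0
    if span < length - 1e-9:
        warnings.warn("series shorter than one segment; nothing to analyze",
                      stacklevel=2)
        return []
    t0 = float(obs.t[0])
    windows = []
    offset = 0.0
    while offset + length <= span + 1e-9:
        if offset > 0 and abs(offset + length - span) <= 1e-9:
            break  # trailing flush window dropped unless it is the only one
        seg = obs.window(t0 + offset, length)
        win = extract.validate_segment(seg)
        windows.append(SegmentWindow(t0 + offset, length, win.valid,
                                     win.reason))
        offset += stride
    return windows


@dataclass
class SegmentEstimate:
    """Optimal parameters for one analysis window."""

    start: float                  # s
    theta: np.ndarray             # 15 parameters, canonical order
    cost: float                   # objective at the optimum
    winner: int                   # index of the winning restart
    n_starts: int
    valid: bool = True

    @property
    def parameters(self) -> ModelParameters:
        return ModelParameters.from_array(self.theta)


#: Random presample pool size per local polish (multi-start screening).
PRESAMPLE_FACTOR = 20


def estimate_segment(seg: SegmentData, bounds: ParameterBounds,
                     config: CostConfig,
                     history: list[tuple[float, np.ndarray]] | None = None,
                     n_starts: int = 5,
                     rng: np.random.Generator | None = None,
                     maxiter: int = 300,
                     warm_starts: list[np.ndarray] | None = None
                     ) -> SegmentEstimate:
    """Multi-start box-constrained minimization of the segment objective.

    Parameters are mapped to the unit box (``θ = lo + x·(hi − lo)``) so the
    L-BFGS-B finite-difference gradients are uniformly scaled.  A pool of
    ``PRESAMPLE_FACTOR·n_starts`` uniform-random points (plus any
    ``warm_starts``, e.g. the previous segment's optimum) is screened by
    objective value and the best ``n_starts`` are polished by L-BFGS-B with
    the analytic gradient — the screening keeps local solves out of the
    saturated-sigmoid plateaus that trap starts with a far-off set point.
    Deterministic given the generator state.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    lo, hi = bounds.as_arrays()
    span = hi - lo
    bounds_hi = dict(zip(PARAM_NAMES, hi))

    def objective(x: np.ndarray) -> float:
        return segment_objective(seg, lo + x * span, config,
                                 history=history, bounds_hi=bounds_hi)

    def objective_grad(x: np.ndarray):
        j, g = segment_objective_grad(seg, lo + x * span, config,
                                      history=history, bounds_hi=bounds_hi)
        return j, g * span

    pool = rng.uniform(0.0, 1.0, (PRESAMPLE_FACTOR * n_starts,
                                  len(PARAM_NAMES)))
    if warm_starts:
        warm = np.clip((np.asarray(warm_starts) - lo) / span, 0.0, 1.0)
        pool = np.vstack([warm, pool])
    pool_vals = np.array([objective(x) for x in pool])
    order = np.argsort(pool_vals)[:n_starts]

    best = None
    for k, j in enumerate(order):
        res = minimize(objective_grad, pool[j], jac=True, method="L-BFGS-B",
                       bounds=[(0.0, 1.0)] * len(PARAM_NAMES),
                       options={"maxiter": maxiter})
        if best is None or res.fun < best[1]:
            best = (k, float(res.fun), res.x)
    winner, cost, x_opt = best
    theta = lo + np.clip(x_opt, 0.0, 1.0) * span
    return SegmentEstimate(seg.t_start, theta, cost, winner, n_starts)


def smooth_trace(estimates: pd.DataFrame, window: int = 5) -> pd.DataFrame:
    """Centred moving average of the per-segment parameter series."""
    cols = [c for c in estimates.columns if c in PARAM_NAMES]
    out = estimates.copy()
    out[cols] = estimates[cols].rolling(window, center=True,
                                        min_periods=1).mean()
    return out


def shock_indices(estimates: pd.DataFrame,
                  segment_length: float = 300.0) -> pd.DataFrame:
    """Derived per-segment clinical markers.

    * ``i_bar_ex`` — scaled volume current over the unstressed venous
      reserve, converted to 1/min; negative values indicate ongoing volume
      loss (hypovolemia).
    * ``m_svr_mid`` — non-autonomic resistance modulation at the segment
      midpoint; negative values indicate vasodilation (distributive state).
    * ``k_max_rel`` — maximal relative contractility, mmHg; low values
      indicate a cardiogenic component.
    """
    mid = segment_length / 2.0
    out = pd.DataFrame({
        "start": estimates["start"],
        "i_bar_ex": estimates["iex_rel"] / estimates["dvv0_rel"] * 60.0,
        "m_svr_mid": np.clip(
            estimates["m_const"] + estimates["m_slope"] * mid, -1.0, 1.0),
        "k_max_rel": estimates["k_max_rel"],
    })
    return out


def reconstruct_observables(theta: np.ndarray, seg: SegmentData) -> dict:
    """Reconstruct Hr, RC and Pp from θ̂ and the measured pressures.

    Returns the reconstructed channels and their Pearson correlation with
    the measured ones; a constant channel yields NaN with a flag.
    """
    _, _, hr_bar, rc_bar, pp_bar = model_channels(seg, np.asarray(theta))
    out = {"hr_bar": hr_bar, "rc_bar": rc_bar, "pp_bar": pp_bar,
           "correlations": {}, "degenerate": {}}
    for name, model, data in (("hr", hr_bar, seg.hr),
                              ("rc", rc_bar, seg.rc),
                              ("pp", pp_bar, seg.pp)):
        if np.std(data) == 0 or np.std(model) == 0:
            out["correlations"][name] = np.nan
            out["degenerate"][name] = True
        else:
            out["correlations"][name] = float(np.corrcoef(model, data)[0, 1])
            out["degenerate"][name] = False
    return out


class ShockStateModel:
    """Inverse model: hidden cardiovascular parameters from observables.

    Parameters
    ----------
    obs : ObservableSeries
        The five observables on the uniform 10 Hz grid.
    meta : PatientMeta
        Age and weight; determines the parameter search ranges.
    config : CostConfig, optional
    bounds : ParameterBounds, optional
        Overrides the age-derived initial search box.

    Examples
    --------
    >>> model = ShockStateModel(obs, PatientMeta(age_years=0.04, weight_kg=3.5))
    >>> res = model.fit(n_starts=5, seed=1)
    >>> res.shock_indices["i_bar_ex"].mean()
    """

    def __init__(self, obs: ObservableSeries, meta: PatientMeta,
                 config: CostConfig | None = None,
                 bounds: ParameterBounds | None = None):
        self.obs = obs
        self.meta = meta
        self.config = config or CostConfig()
        self.initial_bounds = bounds or build_bounds(meta)
        self._dpa, self._dpv = derivative_channels(obs, self.config)
        self.windows = segment_series(obs, self.config.segment_length,
                                      self.config.stride)

    @classmethod
    def from_waveforms(cls, rec: WaveformRecord, meta: PatientMeta,
                       config: CostConfig | None = None,
                       **extract_kw) -> "ShockStateModel":
        """Build the model straight from raw 125 Hz waveforms."""
        obs = extract.extract_observables(rec, **extract_kw)
        return cls(obs, meta, config=config)

    def segment_data(self, window: SegmentWindow,
                     bounds: ParameterBounds | None = None) -> SegmentData:
        b = bounds or self.initial_bounds
        return SegmentData.from_series(
            self.obs, window.start, window.length, self.config,
            iex_upper=b.hi["iex_rel"], dpa=self._dpa, dpv=self._dpv)

    def fit(self, n_starts: int = 5, seed: int = 0, maxiter: int = 200,
            smooth_window: int = 5) -> "ShockStateResults":
        """Estimate every valid segment and assemble the results.

        Bounds tighten as observed extremes accumulate; the memory penalty
        carries earlier estimates forward.  Fully deterministic given
        ``seed`` (per-segment, per-restart streams are spawned from it).
        """
        if n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        bounds = self.initial_bounds.copy()
        history: list[tuple[float, np.ndarray]] = []
        rows = []
        log = []
        n_valid = 0
        for i, win in enumerate(self.windows):
            if not win.valid:
                log.append({"start": win.start, "estimated": False,
                            "reason": win.reason})
                continue
            seg_obs = self.obs.window(win.start, win.length)
            bounds = update_bounds_from_observables(bounds, seg_obs)
            seg = self.segment_data(win, bounds)
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=[seed, i]))
            warm = [history[-1][1]] if history else None
            est = estimate_segment(seg, bounds, self.config,
                                   history=history, n_starts=n_starts,
                                   rng=rng, maxiter=maxiter,
                                   warm_starts=warm)
            history.append((est.start, est.theta))
            row = {"start": est.start, "cost": est.cost,
                   "winner": est.winner}
            row.update(dict(zip(PARAM_NAMES, est.theta)))
            rows.append(row)
            log.append({"start": win.start, "estimated": True,
                        "cost": est.cost, "winner": est.winner})
            n_valid += 1
        if n_valid == 0:
            warnings.warn("no valid segments; empty results", stacklevel=2)
        estimates = pd.DataFrame(
            rows, columns=["start", *PARAM_NAMES, "cost", "winner"])
        return ShockStateResults(self, estimates, pd.DataFrame(log),
                                 final_bounds=bounds,
                                 smooth_window=smooth_window,
                                 n_starts=n_starts, seed=seed)


class ShockStateResults:
    """Fit output: per-segment estimates, smoothed trajectories, indices."""

    def __init__(self, model: ShockStateModel, estimates: pd.DataFrame,
                 log: pd.DataFrame, final_bounds: ParameterBounds,
                 smooth_window: int, n_starts: int, seed: int):
        self.model = model
        self.estimates = estimates
        self.log = log
        self.final_bounds = final_bounds
        self.smooth_window = smooth_window
        self.n_starts = n_starts
        self.seed = seed
        self.smoothed = smooth_trace(estimates, smooth_window)
        self.shock_indices = shock_indices(
            estimates, model.config.segment_length)
        self.smoothed_indices = shock_indices(
            self.smoothed, model.config.segment_length)

    @property
    def n_segments(self) -> int:
        return len(self.estimates)

    def window_summary(self) -> pd.Series:
        """Record-level means and standard errors of the shock indices."""
        idx = self.shock_indices
        n = max(len(idx), 1)
        out = {}
        for c in ("i_bar_ex", "m_svr_mid", "k_max_rel"):
            out[f"{c}_mean"] = float(idx[c].mean()) if len(idx) else np.nan
            out[f"{c}_se"] = (float(idx[c].std(ddof=1) / np.sqrt(n))
                              if len(idx) > 1 else np.nan)
        out["n_segments"] = len(idx)
        return pd.Series(out)

    def reconstruct(self, segment: int) -> dict:
        """Observable reconstruction + correlations for one fitted segment."""
        row = self.estimates.iloc[segment]
        win = SegmentWindow(float(row["start"]),
                            self.model.config.segment_length)
        seg = self.model.segment_data(win, self.final_bounds)
        theta = row[list(PARAM_NAMES)].to_numpy(dtype=float)
        return reconstruct_observables(theta, seg)

    def summary(self) -> str:
        """Human-readable fit summary in the spirit of statsmodels."""
        lines = []
        w = 66
        lines.append("Shock-state inverse model".center(w))
        lines.append("=" * w)
        meta = self.model.meta
        lines.append(f"Patient age: {meta.age_years:.2f} y   "
                     f"weight: {meta.weight_kg:.1f} kg")
        lines.append(f"Windows: {len(self.model.windows)} "
                     f"({self.n_segments} valid/estimated)   "
                     f"restarts: {self.n_starts}   seed: {self.seed}")
        if self.n_segments:
            lines.append(f"Objective (median over segments): "
                         f"{self.estimates['cost'].median():.4g}")
        lines.append("-" * w)
        ws = self.window_summary()
        lines.append("Shock indices (mean +/- SE over segments):")
        lines.append(f"  volume-loss rate  I_ex  {ws['i_bar_ex_mean']:+.4f} "
                     f"+/- {ws['i_bar_ex_se']:.4f} 1/min")
        lines.append(f"  SVR modulation    M_SVR {ws['m_svr_mid_mean']:+.4f} "
                     f"+/- {ws['m_svr_mid_se']:.4f}")
        lines.append(f"  max contractility K_max {ws['k_max_rel_mean']:.1f} "
                     f"+/- {ws['k_max_rel_se']:.1f} mmHg")
        lines.append("-" * w)
        if self.n_segments:
            med = self.estimates[list(PARAM_NAMES)].median()
            lines.append("Median parameter estimates:")
            for name in PARAM_NAMES:
                lo = self.final_bounds.lo[name]
                hi = self.final_bounds.hi[name]
                lines.append(f"  {name:<14s} {med[name]:>12.4g}   "
                             f"bounds [{lo:.4g}, {hi:.4g}]")
        lines.append("=" * w)
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<ShockStateResults: {self.n_segments} segments, "
                f"{self.n_starts} restarts>")
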