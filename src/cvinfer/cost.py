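"""The segment cost function linking observables to hidden parameters.

For a 300-s window of the five observables, each candidate parameter vector
θ implies model values for heart rate, scaled resistance and pulse
pressure, plus two flow-balance residuals built from smoothed derivative
channels.  The objective is the left-Riemann time integral of the weighted,
normalized squared residuals, plus an exponentially-decaying memory penalty
tying slowly-varying parameters to their earlier estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from . import dynamics
from .params import PARAM_NAMES
from .series import ObservableSeries

#: Parameters whose history enters the memory penalty.
MEMORY_PARAMS = ("cv_rel", "dvv0_rel", "p_set", "hr_max", "hr_min",
                 "r_max_scaled", "r_min_scaled")

_IDX = {n: i for i, n in enumerate(PARAM_NAMES)}


@dataclass(frozen=True)
class CostConfig:
    """Weights, normalizers policy and memory settings of the objective."""

    w_h: float = 1.0      # heart-rate residual weight
    w_r: float = 0.2      # resistance residual weight
    w_p: float = 0.2      # pulse-pressure residual weight
    w_i: float = 0.2      # volume-balance residual weight
    w_a: float = 10.0     # arterial-flow residual weight
    beta: float = 0.1     # memory-penalty weight
    tau_memory: float = 500.0   # memory decay constant, s
    segment_length: float = 300.0   # s
    stride: float = 100.0           # s
    deriv_window: float = 30.0      # Savitzky-Golay derivative window, s
    deriv_order: int = 2

    def __post_init__(self) -> None:
        for name in ("w_h", "w_r", "w_p", "w_i", "w_a", "beta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def derivative_channels(obs: ObservableSeries,
                        config: CostConfig) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed first derivatives of the mean pressures, mmHg/s.

    Savitzky–Golay differentiation over a ``deriv_window``-s window; the
    window suppresses beat- and noise-scale jitter that raw differencing
    would amplify in the flow-balance residuals.
    """
    dt = obs.dt
    win = int(round(config.deriv_window / dt))
    win = max(config.deriv_order + 2, win)
    if win % 2 == 0:
        win += 1
    win = min(win, len(obs) if len(obs) % 2 else len(obs) - 1)
    dpa = savgol_filter(obs.pa, win, config.deriv_order, deriv=1, delta=dt)
    dpv = savgol_filter(obs.pv, win, config.deriv_order, deriv=1, delta=dt)
    return dpa, dpv


@dataclass
class SegmentData:
    """One analysis window with precomputed derivative channels and
    normalizers — everything the objective needs besides θ."""

    t_start: float             # absolute segment start, s
    t_local: np.ndarray        # time since segment start, s
    pa: np.ndarray
    pv: np.ndarray
    hr: np.ndarray             # beats/min
    pp: np.ndarray
    rc: np.ndarray
    dpa: np.ndarray            # mmHg/s
    dpv: np.ndarray            # mmHg/s
    dt: float
    n_h: float                 # mean heart rate, beats/min
    n_r: float                 # mean RC, s
    n_p: float                 # mean pulse pressure, mmHg
    n_a: float                 # mean of (hr/60)·pp, mmHg/s
    n_i: float                 # upper bound of the scaled volume current

    @classmethod
    def from_series(cls, obs: ObservableSeries, start: float, length: float,
                    config: CostConfig, iex_upper: float,
                    dpa: np.ndarray | None = None,
                    dpv: np.ndarray | None = None) -> "SegmentData":
        """Slice a window out of a full series.

        Derivative channels may be precomputed on the full series (avoiding
        per-window edge effects) and sliced here; otherwise they are
        computed on the window alone.
        """
        if dpa is None or dpv is None:
            dpa, dpv = derivative_channels(obs, config)
        mask = (obs.t >= start - 1e-9) & (obs.t < start + length - 1e-9)
        pa, pv = obs.pa[mask], obs.pv[mask]
        hr, pp, rc = obs.hr[mask], obs.pp[mask], obs.rc[mask]
        if np.any(pa - pv <= 0):
            raise dynamics.ModelRegimeError(
                "segment contains samples with Pa <= Pv")
        t = obs.t[mask]
        return cls(
            t_start=float(t[0]), t_local=t - t[0],
            pa=pa, pv=pv, hr=hr, pp=pp, rc=rc,
            dpa=np.asarray(dpa)[mask], dpv=np.asarray(dpv)[mask],
            dt=obs.dt,
            n_h=float(np.mean(hr)), n_r=float(np.mean(rc)),
            n_p=float(np.mean(pp)), n_a=float(np.mean(hr / 60.0 * pp)),
            n_i=float(iex_upper),
        )


def model_channels(seg: SegmentData, theta: np.ndarray):
    """Autonomic states and reconstructed observables implied by θ.

    Returns ``(s_tot, ds_tot, hr_model, rc_model, pp_model)`` where the
    model heart rate is in beats/min and ``ds_tot`` in 1/s.
    """
    p_set = theta[_IDX["p_set"]]
    s, m = dynamics.autonomic_drives(
        seg.t_local, theta[_IDX["s_const"]], theta[_IDX["s_slope"]],
        theta[_IDX["m_const"]], theta[_IDX["m_slope"]])
    s_b = dynamics.baroreflex_activation(seg.pa, p_set)
    s_tot = dynamics.total_autonomic_activation(s_b, s)
    hr_model = theta[_IDX["hr_min"]] + (
        theta[_IDX["hr_max"]] - theta[_IDX["hr_min"]]) * s_tot
    r_mod = dynamics.resistance_modulation(s_tot, m)
    rc_model = theta[_IDX["r_min_scaled"]] + (
        theta[_IDX["r_max_scaled"]] - theta[_IDX["r_min_scaled"]]) * r_mod
    k_rel = theta[_IDX["k_min_rel"]] + (
        theta[_IDX["k_max_rel"]] - theta[_IDX["k_min_rel"]]) * s_tot
    pp_model = k_rel * seg.pv / (seg.pa - seg.pv)

    raw_s = theta[_IDX["s_const"]] + theta[_IDX["s_slope"]] * seg.t_local
    ds_dt = np.where((raw_s > 0.0) & (raw_s < 1.0),
                     theta[_IDX["s_slope"]], 0.0)
    dsb_dpa = -dynamics.K_B * s_b * (1.0 - s_b)
    ds_tot = s_tot * (1.0 - s_tot) * dynamics.SIGMOID_GAIN * (
        dsb_dpa * seg.dpa + ds_dt)
    return s_tot, ds_tot, hr_model, rc_model, pp_model


def cost_terms(seg: SegmentData, theta: np.ndarray):
    """The five residual arrays (f_H, f_R, f_P, f_I, f_a) along the window.

    f_H (beats/min), f_R (s) and f_P (mmHg) compare model to measured
    heart rate, scaled resistance and pulse pressure.  f_I (mmHg/s) is the
    scaled volume-balance residual; f_a (mmHg/s) is the arterial-flow
    residual, with heart rate converted to beats/s.
    """
    theta = np.asarray(theta, dtype=float)
    s_tot, ds_tot, hr_model, rc_model, pp_model = model_channels(seg, theta)
    f_h = hr_model - seg.hr
    f_r = rc_model - seg.rc
    f_p = pp_model - seg.pp
    f_i = (seg.dpa + theta[_IDX["cv_rel"]] * seg.dpv
           - theta[_IDX["dvv0_rel"]] * ds_tot - theta[_IDX["iex_rel"]])
    f_a = (seg.hr / 60.0 * seg.pp
           - (seg.pa - seg.pv) * theta[_IDX["alpha_rc"]] / rc_model
           - seg.dpa)
    return f_h, f_r, f_p, f_i, f_a


def history_penalty(theta: np.ndarray, t_start: float,
                    history: list[tuple[float, np.ndarray]],
                    bounds_hi: dict[str, float],
                    config: CostConfig) -> float:
    """Exponentially decaying pull towards earlier estimates of θ*.

    Each past estimate contributes ``exp(-(t - t̄)/τ)·(θ̂_i(t̄) - θ_i)²/B_i²``
    for the slowly-varying parameters, where B_i is the parameter's upper
    bound.  Recent segments dominate; the weight decays with age.
    """
    if not history or config.beta == 0.0:
        return 0.0
    pen = 0.0
    for t_bar, theta_past in history:
        w = np.exp(-(t_start - t_bar) / config.tau_memory)
        for name in MEMORY_PARAMS:
            i = _IDX[name]
            pen += w * (theta_past[i] - theta[i]) ** 2 / bounds_hi[name] ** 2
    return config.beta * pen


def segment_objective_grad(seg: SegmentData, theta: np.ndarray,
                           config: CostConfig,
                           history: list[tuple[float, np.ndarray]] | None = None,
                           bounds_hi: dict[str, float] | None = None
                           ) -> tuple[float, np.ndarray]:
    """Objective value and its analytic gradient with respect to θ.

    All residuals are smooth, explicit functions of the parameters (the
    drive-clipping indicators are piecewise-constant), so the gradient is
    assembled by the chain rule through the three sigmoids.  Used by the
    optimizer; agreement with finite differences is asserted in the tests.
    """
    theta = np.asarray(theta, dtype=float)
    g = dynamics.SIGMOID_GAIN
    kb = dynamics.K_B
    t = seg.t_local
    n_par = len(PARAM_NAMES)

    p_set = theta[_IDX["p_set"]]
    cv = theta[_IDX["cv_rel"]]
    dvv0 = theta[_IDX["dvv0_rel"]]
    iex = theta[_IDX["iex_rel"]]
    h_lo, h_hi = theta[_IDX["hr_min"]], theta[_IDX["hr_max"]]
    r_lo, r_hi = theta[_IDX["r_min_scaled"]], theta[_IDX["r_max_scaled"]]
    k_lo, k_hi = theta[_IDX["k_min_rel"]], theta[_IDX["k_max_rel"]]
    s_c, s_s = theta[_IDX["s_const"]], theta[_IDX["s_slope"]]
    m_c, m_s = theta[_IDX["m_const"]], theta[_IDX["m_slope"]]
    alpha = theta[_IDX["alpha_rc"]]

    raw_s = s_c + s_s * t
    ind_s = ((raw_s > 0.0) & (raw_s < 1.0)).astype(float)
    s = np.clip(raw_s, 0.0, 1.0)
    raw_m = m_c + m_s * t
    ind_m = ((raw_m > -1.0) & (raw_m < 1.0)).astype(float)
    m = np.clip(raw_m, -1.0, 1.0)

    q = 1.0 / (1.0 + np.exp(-kb * (seg.pa - p_set)))   # 1 - S_b
    s_b = 1.0 - q
    s_tot = 1.0 / (1.0 + np.exp(-g * (s_b + s - 1.0)))
    a_tot = s_tot * (1.0 - s_tot)
    r_mod = 1.0 / (1.0 + np.exp(-g * (s_tot + m)))
    c_mod = r_mod * (1.0 - r_mod)

    dsb_dpset = kb * s_b * (1.0 - s_b)
    # ∂S_tot/∂θ for the three parameters it depends on
    dstot = np.zeros((n_par, t.size))
    dstot[_IDX["p_set"]] = a_tot * g * dsb_dpset
    dstot[_IDX["s_const"]] = a_tot * g * ind_s
    dstot[_IDX["s_slope"]] = a_tot * g * t * ind_s
    # ∂R_mod/∂θ
    drmod = c_mod * g * dstot
    drmod[_IDX["m_const"]] += c_mod * g * ind_m
    drmod[_IDX["m_slope"]] += c_mod * g * t * ind_m

    hr_model = h_lo + (h_hi - h_lo) * s_tot
    rc_model = r_lo + (r_hi - r_lo) * r_mod
    w_pp = seg.pv / (seg.pa - seg.pv)
    pp_model = (k_lo + (k_hi - k_lo) * s_tot) * w_pp

    dsb_dpa = -kb * s_b * (1.0 - s_b)
    b_term = dsb_dpa * seg.dpa + s_s * ind_s
    ds_tot_dt = a_tot * g * b_term

    f_h = hr_model - seg.hr
    f_r = rc_model - seg.rc
    f_p = pp_model - seg.pp
    f_i = seg.dpa + cv * seg.dpv - dvv0 * ds_tot_dt - iex
    f_a = seg.hr / 60.0 * seg.pp - (seg.pa - seg.pv) * alpha / rc_model - seg.dpa

    # residual jacobians (n_par, n)
    df_h = (h_hi - h_lo) * dstot
    df_h[_IDX["hr_min"]] += 1.0 - s_tot
    df_h[_IDX["hr_max"]] += s_tot

    df_r = (r_hi - r_lo) * drmod
    df_r[_IDX["r_min_scaled"]] += 1.0 - r_mod
    df_r[_IDX["r_max_scaled"]] += r_mod

    df_p = (k_hi - k_lo) * w_pp * dstot
    df_p[_IDX["k_min_rel"]] += (1.0 - s_tot) * w_pp
    df_p[_IDX["k_max_rel"]] += s_tot * w_pp

    # d(dS_tot/dt)/dθ = g[(1-2S_tot)·∂S_tot/∂θ·B + A·∂B/∂θ]
    dds = g * (1.0 - 2.0 * s_tot) * b_term * dstot
    dds[_IDX["p_set"]] += g * a_tot * (-kb * (1.0 - 2.0 * s_b)
                                       * dsb_dpset * seg.dpa)
    dds[_IDX["s_slope"]] += g * a_tot * ind_s

    df_i = -dvv0 * dds
    df_i[_IDX["cv_rel"]] += seg.dpv
    df_i[_IDX["dvv0_rel"]] += -ds_tot_dt
    df_i[_IDX["iex_rel"]] += -1.0

    gap_term = (seg.pa - seg.pv) * alpha / rc_model ** 2
    df_a = gap_term * df_r          # ∂rc_model/∂θ coincides with ∂f_r/∂θ
    df_a[_IDX["alpha_rc"]] += -(seg.pa - seg.pv) / rc_model

    integrand = (config.w_h * f_h ** 2 / seg.n_h
                 + config.w_r * f_r ** 2 / seg.n_r
                 + config.w_p * f_p ** 2 / seg.n_p
                 + config.w_i * f_i ** 2 / seg.n_i
                 + config.w_a * f_a ** 2 / seg.n_a)
    j = float(np.sum(integrand) * seg.dt)

    grad = seg.dt * 2.0 * (
        (config.w_h / seg.n_h) * df_h @ f_h
        + (config.w_r / seg.n_r) * df_r @ f_r
        + (config.w_p / seg.n_p) * df_p @ f_p
        + (config.w_i / seg.n_i) * df_i @ f_i
        + (config.w_a / seg.n_a) * df_a @ f_a)

    if history:
        if bounds_hi is None:
            raise ValueError("bounds_hi required when history is supplied")
        for t_bar, theta_past in history:
            wmem = np.exp(-(seg.t_start - t_bar) / config.tau_memory)
            for name in MEMORY_PARAMS:
                i = _IDX[name]
                diff = theta_past[i] - theta[i]
                j += config.beta * wmem * diff ** 2 / bounds_hi[name] ** 2
                grad[i] += -2.0 * config.beta * wmem * diff / bounds_hi[name] ** 2
    return j, grad


def segment_objective(seg: SegmentData, theta: np.ndarray,
                      config: CostConfig,
                      history: list[tuple[float, np.ndarray]] | None = None,
                      bounds_hi: dict[str, float] | None = None) -> float:
    """The scalar objective J(θ) for one segment.

    Left-Riemann integral of the weighted normalized squared residuals on
    the 10 Hz grid, plus the memory penalty when a history is supplied.
    """
    f_h, f_r, f_p, f_i, f_a = cost_terms(seg, theta)
    integrand = (config.w_h * f_h ** 2 / seg.n_h
                 + config.w_r * f_r ** 2 / seg.n_r
                 + config.w_p * f_p ** 2 / seg.n_p
                 + config.w_i * f_i ** 2 / seg.n_i
                 + config.w_a * f_a ** 2 / seg.n_a)
    j = float(np.sum(integrand) * seg.dt)
    if history:
        if bounds_hi is None:
            raise ValueError("bounds_hi required when history is supplied")
        j += history_penalty(theta, seg.t_start, history, bounds_hi, config)
    return j
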