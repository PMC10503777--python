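"""Algebraic and differential equations of the pressure-form model.

The circulation is reduced to two dynamical variables — mean arterial
pressure ``P_a`` and mean venous pressure ``P_v`` — with all volumes
eliminated in favour of pressures via the compartment compliances:

    Ca·dPa/dt = Ca·Hr·Pp − (Pa − Pv)/R
    Ca·dPa/dt + Cv·dPv/dt − ΔVv0·dStot/dt = Iex

Heart rate, peripheral resistance, contractility and the unstressed venous
volume are all slaved to the total autonomic activation ``S_tot``, a sigmoid
blend of the baroreflex ``S_b(P_a)`` and the pressure-independent drive
``S(t)``.  All functions accept scalars or numpy arrays.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .params import K_B, SIGMOID_GAIN, PhysicalParameters


class ModelRegimeError(ValueError):
    """Raised when the model leaves its valid pressure regime (Pa <= Pv)."""


#: Minimal arterial-venous pressure gap (mmHg) accepted by the
#: contractility/pulse-pressure relation before raising.
MIN_PRESSURE_GAP = 0.5


def _logistic(x):
    return expit(x)


def _check_finite(name, *vals) -> None:
    for v in vals:
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{name}: non-finite input")


def baroreflex_activation(p_a, p_set, k_b: float = K_B):
    """Baroreflex drive S_b = 1 − σ(k_b·(Pa − P_set)), in (0, 1).

    Decreasing in ``p_a``: high arterial pressure silences the reflex,
    low pressure activates it.  ``S_b(P_set) = 0.5``.
    """
    _check_finite("baroreflex_activation", p_a, p_set, k_b)
    if k_b <= 0:
        raise ValueError("k_b must be positive")
    return 1.0 - _logistic(k_b * (np.asarray(p_a, dtype=float) - p_set))


def baroreflex_slope(p_a, p_set, k_b: float = K_B):
    """dS_b/dPa — analytic derivative, −k_b·S_b·(1−S_b)."""
    s_b = baroreflex_activation(p_a, p_set, k_b)
    return -k_b * s_b * (1.0 - s_b)


def total_autonomic_activation(s_b, s):
    """Total autonomic activation S_tot = σ(3.3·(S_b + S − 1)), in (0, 1).

    Approximately the mean of its two inputs; equals 0.5 when they sum to 1.
    """
    s_b = np.asarray(s_b, dtype=float)
    s = np.asarray(s, dtype=float)
    _check_finite("total_autonomic_activation", s_b, s)
    if np.any(s_b < 0) or np.any(s_b > 1) or np.any(s < 0) or np.any(s > 1):
        raise ValueError("S_b and S must lie in [0, 1]")
    return _logistic(SIGMOID_GAIN * (s_b + s - 1.0))


def heart_rate(s_tot, hr_min, hr_max):
    """Heart rate in beats/min, linear in the autonomic activation."""
    s_tot = np.asarray(s_tot, dtype=float)
    _check_finite("heart_rate", s_tot, hr_min, hr_max)
    if np.any(s_tot < 0) or np.any(s_tot > 1):
        raise ValueError("S_tot must lie in [0, 1]")
    if not np.all(np.asarray(hr_min) < np.asarray(hr_max)):
        raise ValueError("hr_min must be < hr_max")
    return hr_min + (hr_max - hr_min) * s_tot


def resistance_modulation(s_tot, m_svr):
    """SVR modulation R_mod = σ(3.3·(S_tot + M_SVR)), in (0, 1)."""
    s_tot = np.asarray(s_tot, dtype=float)
    m_svr = np.asarray(m_svr, dtype=float)
    _check_finite("resistance_modulation", s_tot, m_svr)
    if np.any(s_tot < 0) or np.any(s_tot > 1):
        raise ValueError("S_tot must lie in [0, 1]")
    if np.any(m_svr < -1) or np.any(m_svr > 1):
        raise ValueError("M_SVR must lie in [-1, 1]")
    return _logistic(SIGMOID_GAIN * (s_tot + m_svr))


def peripheral_resistance(s_tot, m_svr, r_min, r_max):
    """Peripheral resistance (physical or scaled, depending on the bounds)."""
    return r_min + (r_max - r_min) * resistance_modulation(s_tot, m_svr)


def pulse_pressure_model(s_tot, k_min_rel, k_max_rel, p_a, p_v):
    """Pulse pressure from the contractility chain.

    ``Pp = K̃(S_tot)·Pv/(Pa − Pv)`` with the relative contractility
    ``K̃ = K̃min + (K̃max − K̃min)·S_tot``.  The venous pressure stands in for
    the end-diastolic filling pressure, so the expression degrades when
    ``Pv`` approaches ``Pa``; a minimal gap is enforced.
    """
    p_a = np.asarray(p_a, dtype=float)
    p_v = np.asarray(p_v, dtype=float)
    _check_finite("pulse_pressure_model", s_tot, k_min_rel, k_max_rel, p_a, p_v)
    if np.any(p_v < 0):
        raise ModelRegimeError("venous pressure fell below zero")
    if np.any(p_a - p_v < MIN_PRESSURE_GAP):
        raise ModelRegimeError(
            f"arterial-venous gap below {MIN_PRESSURE_GAP} mmHg: "
            "pulse-pressure relation is singular"
        )
    k_rel = k_min_rel + (k_max_rel - k_min_rel) * np.asarray(s_tot, dtype=float)
    return k_rel * p_v / (p_a - p_v)


def autonomic_drives(t, s_const, s_slope, m_const, m_slope):
    """Linear-in-time independent drives, clipped to their ranges.

    Returns ``(S(t), M_SVR(t))`` with ``S`` clipped to [0, 1] and ``M_SVR``
    to [-1, 1].  ``t`` is measured from the segment or scenario origin.
    """
    t = np.asarray(t, dtype=float)
    s = np.clip(s_const + s_slope * t, 0.0, 1.0)
    m = np.clip(m_const + m_slope * t, -1.0, 1.0)
    return s, m


def pressure_derivatives(t, p_a, p_v, params: PhysicalParameters,
                         s=None, ds_dt=None, m_svr=None, i_ex=None):
    """Right-hand side of the two pressure ODEs.

    Parameters
    ----------
    t : float
        Time, s.
    p_a, p_v : float
        Current arterial and venous pressures, mmHg.
    params : PhysicalParameters
    s, ds_dt, m_svr, i_ex : float, optional
        Instantaneous independent drive, its time derivative, SVR modulation
        and external volume current.  Default to the linear drives encoded
        in ``params`` (with clipping) and ``params.i_ex``.

    Returns
    -------
    (dPa/dt, dPv/dt) : tuple of float, mmHg/s

    Notes
    -----
    ``dS_tot/dt`` is evaluated analytically by the chain rule through the
    two sigmoids; it depends on ``dPa/dt``, which is available first because
    the arterial equation does not involve ``dPv/dt``.
    """
    if s is None or m_svr is None:
        s_lin, m_lin = autonomic_drives(
            t, params.s_const, params.s_slope, params.m_const, params.m_slope)
        if s is None:
            s = s_lin
            raw = params.s_const + params.s_slope * t
            ds_dt = params.s_slope if 0.0 < raw < 1.0 else 0.0
        if m_svr is None:
            m_svr = m_lin
    if ds_dt is None:
        ds_dt = 0.0
    if i_ex is None:
        i_ex = params.i_ex

    if p_a - p_v < MIN_PRESSURE_GAP:
        raise ModelRegimeError(
            f"Pa - Pv = {p_a - p_v:.3g} mmHg at t = {t:.3g} s")

    s_b = baroreflex_activation(p_a, params.p_set, params.k_b)
    s_tot = total_autonomic_activation(s_b, s)
    hr_bps = heart_rate(s_tot, params.hr_min, params.hr_max) / 60.0
    r = peripheral_resistance(s_tot, m_svr, params.r_min, params.r_max)
    p_p = pulse_pressure_model(
        s_tot, params.k_min_rel, params.k_max_rel, p_a, p_v)

    dpa = hr_bps * p_p - (p_a - p_v) / (params.c_a * r)

    # chain rule: dStot/dt = Stot(1-Stot)·g·(dSb/dPa·dPa/dt + dS/dt)
    dsb_dpa = -params.k_b * s_b * (1.0 - s_b)
    dstot = s_tot * (1.0 - s_tot) * SIGMOID_GAIN * (dsb_dpa * dpa + ds_dt)

    dpv = (i_ex - params.c_a * dpa + params.dv_v0 * dstot) / params.c_v
    return dpa, dpv
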