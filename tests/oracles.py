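"""Independent straight-loop oracles used by multiple test modules."""

import math

from cvinfer.params import PARAM_NAMES

IDX = {n: i for i, n in enumerate(PARAM_NAMES)}


def naive_objective(seg, theta, config, history=None, bounds_hi=None):
    """Straight-loop re-implementation of the objective, scalar math only.

    Deliberately element-wise and unvectorized: the independent oracle for
    the vectorized implementation.
    """
    kb = 0.1838
    g = 3.3
    total = 0.0
    for i in range(len(seg.t_local)):
        t = seg.t_local[i]
        pa, pv = seg.pa[i], seg.pv[i]
        s_raw = theta[IDX["s_const"]] + theta[IDX["s_slope"]] * t
        s = min(1.0, max(0.0, s_raw))
        m_raw = theta[IDX["m_const"]] + theta[IDX["m_slope"]] * t
        m = min(1.0, max(-1.0, m_raw))
        s_b = 1.0 - 1.0 / (1.0 + math.exp(-kb * (pa - theta[IDX["p_set"]])))
        s_tot = 1.0 / (1.0 + math.exp(-g * (s_b + s - 1.0)))
        r_mod = 1.0 / (1.0 + math.exp(-g * (s_tot + m)))
        hr_mod = theta[IDX["hr_min"]] + (
            theta[IDX["hr_max"]] - theta[IDX["hr_min"]]) * s_tot
        rc_mod = theta[IDX["r_min_scaled"]] + (
            theta[IDX["r_max_scaled"]] - theta[IDX["r_min_scaled"]]) * r_mod
        pp_mod = (theta[IDX["k_min_rel"]] + (
            theta[IDX["k_max_rel"]] - theta[IDX["k_min_rel"]]) * s_tot) * \
            pv / (pa - pv)
        ds = theta[IDX["s_slope"]] if 0.0 < s_raw < 1.0 else 0.0
        dsb = -kb * s_b * (1.0 - s_b) * seg.dpa[i]
        dstot = s_tot * (1.0 - s_tot) * g * (dsb + ds)
        f_h = hr_mod - seg.hr[i]
        f_r = rc_mod - seg.rc[i]
        f_p = pp_mod - seg.pp[i]
        f_i = (seg.dpa[i] + theta[IDX["cv_rel"]] * seg.dpv[i]
               - theta[IDX["dvv0_rel"]] * dstot - theta[IDX["iex_rel"]])
        f_a = (seg.hr[i] / 60.0 * seg.pp[i]
               - (pa - pv) * theta[IDX["alpha_rc"]] / rc_mod - seg.dpa[i])
        total += seg.dt * (config.w_h * f_h ** 2 / seg.n_h
                           + config.w_r * f_r ** 2 / seg.n_r
                           + config.w_p * f_p ** 2 / seg.n_p
                           + config.w_i * f_i ** 2 / seg.n_i
                           + config.w_a * f_a ** 2 / seg.n_a)
    if history:
        from cvinfer.cost import MEMORY_PARAMS
        for t_bar, th_past in history:
            w = math.exp(-(seg.t_start - t_bar) / config.tau_memory)
            for name in MEMORY_PARAMS:
                total += config.beta * w * (
                    th_past[IDX[name]] - theta[IDX[name]]) ** 2 / \
                    bounds_hi[name] ** 2
    return total
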