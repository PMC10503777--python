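"""Forward simulation of shock scenarios.

Integrates the two pressure ODEs with fixed-step RK4 under piecewise-linear
schedules for the external volume current ``I_ex(t)``, the non-autonomic
resistance modulation ``M_SVR(t)`` and the independent autonomic drive
``S(t)``.  Emits full hidden-state traces plus the five observables
down-sampled to the estimator's native 10 Hz grid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import dynamics
from .dynamics import ModelRegimeError
from .params import PhysicalParameters, SIMULATION_REFERENCE
from .series import OBSERVABLE_HZ, ObservableSeries


class DivergenceError(RuntimeError):
    """Raised when a trajectory blows up (|P| beyond the physical range)."""


#: Pressure magnitude treated as numerical blow-up, mmHg.
BLOWUP_PRESSURE = 500.0


@dataclass(frozen=True)
class PiecewiseLinear:
    """Piecewise-linear schedule with optional range clipping.

    ``knots`` is a sequence of (time, value) pairs with strictly increasing
    times; the schedule is constant before the first and after the last knot.
    """

    knots: tuple[tuple[float, float], ...]
    lo: float = -np.inf
    hi: float = np.inf

    def __post_init__(self) -> None:
        ts = np.array([k[0] for k in self.knots], dtype=float)
        vs = np.array([k[1] for k in self.knots], dtype=float)
        if ts.size == 0:
            raise ValueError("schedule needs at least one knot")
        if np.any(np.diff(ts) <= 0):
            raise ValueError("knot times must be strictly increasing")
        if not np.all(np.isfinite(vs)):
            raise ValueError("knot values must be finite")
        object.__setattr__(self, "_ts", ts)
        object.__setattr__(self, "_vs", vs)

    @classmethod
    def constant(cls, value: float, lo: float = -np.inf,
                 hi: float = np.inf) -> "PiecewiseLinear":
        return cls(((0.0, value),), lo=lo, hi=hi)

    def value(self, t):
        raw = np.interp(t, self._ts, self._vs)
        return np.clip(raw, self.lo, self.hi)

    def shifted(self, offset: float) -> "PiecewiseLinear":
        """The same schedule delayed by ``offset`` seconds."""
        return PiecewiseLinear(tuple((t + offset, v) for t, v in self.knots),
                               lo=self.lo, hi=self.hi)

    def slope(self, t):
        """Local slope; zero outside the knot span and where clipping binds."""
        t_arr = np.asarray(t, dtype=float)
        idx = np.searchsorted(self._ts, t_arr, side="right")
        with np.errstate(invalid="ignore"):
            dv = np.diff(self._vs)
            dt = np.diff(self._ts)
        seg_slopes = dv / dt if dt.size else np.array([])
        slopes = np.zeros_like(t_arr, dtype=float)
        inside = (idx >= 1) & (idx < self._ts.size)
        if seg_slopes.size:
            slopes[inside] = seg_slopes[np.clip(idx[inside] - 1, 0,
                                                seg_slopes.size - 1)]
        raw = np.interp(t_arr, self._ts, self._vs)
        slopes[(raw <= self.lo) | (raw >= self.hi)] = 0.0
        return slopes if slopes.ndim else float(slopes)


@dataclass(frozen=True)
class Scenario:
    """A named shock scenario: drive schedules over ``[0, duration]``."""

    name: str
    duration: float                      # s
    i_ex: PiecewiseLinear                # ml/s
    s: PiecewiseLinear                   # dimensionless in [0, 1]
    m_svr: PiecewiseLinear               # dimensionless in [-1, 1]

    def with_duration(self, duration: float) -> "Scenario":
        return replace(self, duration=duration)

    def delayed(self, offset: float) -> "Scenario":
        """Delay every drive schedule by ``offset`` s and extend the run."""
        return Scenario(self.name, self.duration + offset,
                        self.i_ex.shifted(offset), self.s.shifted(offset),
                        self.m_svr.shifted(offset))


TRACE_COLUMNS = ("t", "pa", "pv", "hr", "pp", "rc", "sb", "stot",
                 "rmod", "iex", "s", "msvr")


@dataclass
class SimulationTrace:
    """Full simulation output: observables plus hidden autonomic states."""

    frame: pd.DataFrame                 # columns TRACE_COLUMNS, one row per step
    params: PhysicalParameters
    scenario: Scenario
    dt: float

    def __getattr__(self, name):
        if name in TRACE_COLUMNS:
            return self.frame[name].to_numpy()
        raise AttributeError(name)

    def observables(self, hz: float = OBSERVABLE_HZ,
                    noise_sd: dict[str, float] | None = None,
                    seed: int | None = None) -> ObservableSeries:
        """Down-sample to the estimator grid, optionally adding noise.

        ``noise_sd`` maps channel names (pa, pv, hr, pp, rc) to additive
        Gaussian SDs; the default is noiseless.
        """
        t = self.frame["t"].to_numpy()
        grid = np.arange(t[0], t[-1] + 1e-9, 1.0 / hz)
        chans = {}
        for c in ("pa", "pv", "hr", "pp", "rc"):
            chans[c] = np.interp(grid, t, self.frame[c].to_numpy())
        if noise_sd:
            rng = np.random.default_rng(seed)
            for c, sd in noise_sd.items():
                if sd > 0:
                    chans[c] = chans[c] + rng.normal(0.0, sd, grid.size)
        return ObservableSeries(grid, chans["pa"], chans["pv"],
                                chans["hr"], chans["pp"], chans["rc"])

    def conserved_volume(self) -> np.ndarray:
        """See :func:`conserved_volume`."""
        return conserved_volume(self, self.params)


def _rhs(t: float, p_a: float, p_v: float, params: PhysicalParameters,
         scen: Scenario) -> tuple[float, float]:
    s = float(scen.s.value(t))
    ds = float(scen.s.slope(t))
    m = float(scen.m_svr.value(t))
    iex = float(scen.i_ex.value(t))
    return dynamics.pressure_derivatives(
        t, p_a, p_v, params, s=s, ds_dt=ds, m_svr=m, i_ex=iex)


def simulate(params: PhysicalParameters | None = None,
             scenario: Scenario | str = "control",
             dt: float = 0.1,
             initial: tuple[float, float] = (48.0, 4.0)) -> SimulationTrace:
    """Integrate the model forward with fixed-step RK4.

    Parameters
    ----------
    params : PhysicalParameters, optional
        Defaults to the printed reference parameter set.
    scenario : Scenario or str
        A scenario object or a name understood by :func:`scenario_library`.
    dt : float
        Integration step, s.
    initial : (float, float)
        Initial (Pa, Pv) in mmHg; defaults to (48, 4).

    Raises
    ------
    ModelRegimeError
        If the arterial-venous gap collapses (time of failure in message).
    DivergenceError
        If a pressure exceeds 500 mmHg in magnitude.
    """
    if params is None:
        params = SIMULATION_REFERENCE
    if isinstance(scenario, str):
        scenario = scenario_library()[scenario]
    if dt <= 0:
        raise ValueError("dt must be positive")

    n_steps = int(round(scenario.duration / dt))
    t_grid = np.arange(n_steps + 1) * dt
    pa = np.empty(n_steps + 1)
    pv = np.empty(n_steps + 1)
    pa[0], pv[0] = initial

    for i in range(n_steps):
        t = t_grid[i]
        a, v = pa[i], pv[i]
        try:
            k1 = _rhs(t, a, v, params, scenario)
            k2 = _rhs(t + dt / 2, a + dt / 2 * k1[0], v + dt / 2 * k1[1],
                      params, scenario)
            k3 = _rhs(t + dt / 2, a + dt / 2 * k2[0], v + dt / 2 * k2[1],
                      params, scenario)
            k4 = _rhs(t + dt, a + dt * k3[0], v + dt * k3[1], params, scenario)
        except ModelRegimeError as err:
            raise ModelRegimeError(f"at t = {t:.2f} s: {err}") from err
        pa[i + 1] = a + dt / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        pv[i + 1] = v + dt / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        if abs(pa[i + 1]) > BLOWUP_PRESSURE or abs(pv[i + 1]) > BLOWUP_PRESSURE:
            raise DivergenceError(
                f"pressure blow-up at t = {t_grid[i + 1]:.2f} s")

    s = np.asarray(scenario.s.value(t_grid), dtype=float)
    m = np.asarray(scenario.m_svr.value(t_grid), dtype=float)
    iex = np.asarray(scenario.i_ex.value(t_grid), dtype=float)
    sb = dynamics.baroreflex_activation(pa, params.p_set, params.k_b)
    stot = dynamics.total_autonomic_activation(sb, s)
    hr = dynamics.heart_rate(stot, params.hr_min, params.hr_max)
    rmod = dynamics.resistance_modulation(stot, m)
    r = params.r_min + (params.r_max - params.r_min) * rmod
    pp = dynamics.pulse_pressure_model(
        stot, params.k_min_rel, params.k_max_rel, pa, pv)
    rc = params.alpha_rc * params.c_a * r

    frame = pd.DataFrame({
        "t": t_grid, "pa": pa, "pv": pv, "hr": hr, "pp": pp, "rc": rc,
        "sb": sb, "stot": stot, "rmod": rmod, "iex": iex, "s": s, "msvr": m,
    })
    return SimulationTrace(frame, params, scenario, dt)


def conserved_volume(trace: SimulationTrace,
                     params: PhysicalParameters) -> np.ndarray:
    """Stressed-volume bookkeeping series V(t) = Ca·Pa + Cv·Pv − ΔVv0·S_tot.

    Along an exact trajectory, ``V(t) − V(0)`` equals the integral of the
    external current ``I_ex``; deviations measure integrator error.
    """
    return (params.c_a * trace.pa + params.c_v * trace.pv
            - params.dv_v0 * trace.stot)


# ---------------------------------------------------------------------------
# scenario library


def scenario_library(duration: float = 1500.0,
                     iex_peak: float = -0.05,
                     msvr_drop: float = -0.5,
                     ramp: float = 900.0) -> dict[str, Scenario]:
    """Named scenarios mirroring the reference simulation set-up.

    * ``control`` — all drives constant (S = 0.2, M = 0, I_ex = 0).
    * ``hypovolemic`` — external current ramps to ``iex_peak`` ml/s within
      the first minute and holds through the 15-min withdrawal, then stops.
    * ``distributive`` — M_SVR declines linearly to ``msvr_drop`` over
      15 min; volume constant.
    * ``combined`` — both insults superposed.
    * ``fight_or_flight`` — the independent autonomic drive S steps up
      0.2 → 0.8 over two minutes, mid-record.
    """
    s0 = 0.2
    const = lambda v, lo, hi: PiecewiseLinear.constant(v, lo=lo, hi=hi)
    s_const = const(s0, 0.0, 1.0)
    m_const = const(0.0, -1.0, 1.0)
    iex_zero = const(0.0, -np.inf, np.inf)

    iex_hypo = PiecewiseLinear(
        ((0.0, 0.0), (60.0, iex_peak), (ramp, iex_peak), (ramp + 60.0, 0.0)))
    m_dist = PiecewiseLinear(((0.0, 0.0), (ramp, msvr_drop)), lo=-1.0, hi=1.0)
    s_fof = PiecewiseLinear(((300.0, s0), (420.0, 0.8)), lo=0.0, hi=1.0)

    lib = {
        "control": Scenario("control", duration, iex_zero, s_const, m_const),
        "hypovolemic": Scenario("hypovolemic", duration, iex_hypo, s_const,
                                m_const),
        "distributive": Scenario("distributive", duration, iex_zero, s_const,
                                 m_dist),
        "combined": Scenario("combined", duration, iex_hypo, s_const, m_dist),
        "fight_or_flight": Scenario("fight_or_flight", duration, iex_zero,
                                    s_fof, m_const),
    }
    return lib


def get_scenario(name: str, **kw) -> Scenario:
    lib = scenario_library(**kw)
    try:
        return lib[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(lib)}") from None
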