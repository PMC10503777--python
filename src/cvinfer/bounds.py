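"""Age- and weight-dependent search ranges for the hidden parameters.

Ranges for the baroreflex set point and the heart-rate extremes come from
pediatric reference percentiles and depend on the age bracket; the
volume-related ranges are anchored to per-kg blood volume (100 ml/kg for
infants up to 3 months, 75 ml/kg beyond) and the physiological span of
arterial compliance per kg, C ∈ [0.02, 0.15] ml/(mmHg·kg).  Because the
estimated quantities are all scaled by the (unknown) arterial compliance,
the body weight cancels everywhere and the intervals depend on age only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .params import PARAM_NAMES, PatientMeta
from .series import ObservableSeries

#: Arterial compliance per kg, ml/(mmHg·kg).
C_MIN = 0.02
C_MAX = 0.15

#: Blood volume per kg, ml/kg.
BLOOD_VOLUME_INFANT = 100.0   # age <= 3 months
BLOOD_VOLUME_OLDER = 75.0

#: Unstressed venous reserve as a fraction of blood volume.
UNSTRESSED_FRACTION = (0.1, 0.3)

#: Maximal external volume change per hour, fraction of blood volume.
MAX_VOLUME_RATE_PER_HOUR = 0.25

# (upper age in months, [lo, hi]) — evaluated in order.
_P_SET_BRACKETS = (
    (1, (42.0, 73.0)), (3, (44.0, 76.0)), (6, (52.0, 80.0)),
    (12, (52.0, 86.0)), (36, (56.0, 88.0)), (72, (55.0, 83.0)),
    (108, (58.0, 87.0)), (132, (59.0, 87.0)), (180, (59.0, 89.0)),
    (np.inf, (60.0, 91.0)),
)
_HR_MIN_BRACKETS = (
    (6, (110.0, 130.0)), (12, (90.0, 130.0)), (36, (80.0, 110.0)),
    (72, (75.0, 110.0)), (132, (65.0, 110.0)), (np.inf, (60.0, 90.0)),
)
_HR_MAX_BRACKETS = (
    (6, (150.0, 180.0)), (12, (145.0, 180.0)), (36, (140.0, 180.0)),
    (72, (130.0, 160.0)), (108, (125.0, 160.0)), (132, (120.0, 160.0)),
    (180, (115.0, 160.0)), (np.inf, (110.0, 150.0)),
)


def _bracket(table, age_months: float) -> tuple[float, float]:
    for hi, interval in table:
        if age_months < hi:
            return interval
    return table[-1][1]


@dataclass
class ParameterBounds:
    """Box constraints [lo, hi] for each of the 15 estimated parameters."""

    lo: dict[str, float]
    hi: dict[str, float]

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            if name not in self.lo or name not in self.hi:
                raise ValueError(f"missing bounds for {name}")
            if not self.lo[name] < self.hi[name]:
                raise ValueError(
                    f"empty interval for {name}: "
                    f"[{self.lo[name]}, {self.hi[name]}]")

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return (np.array([self.lo[n] for n in PARAM_NAMES]),
                np.array([self.hi[n] for n in PARAM_NAMES]))

    def contains(self, theta: np.ndarray, atol: float = 1e-9) -> bool:
        lo, hi = self.as_arrays()
        theta = np.asarray(theta, dtype=float)
        return bool(np.all(theta >= lo - atol) and np.all(theta <= hi + atol))

    def copy(self) -> "ParameterBounds":
        return ParameterBounds(dict(self.lo), dict(self.hi))


def build_bounds(meta: PatientMeta) -> ParameterBounds:
    """Initial search box from patient age (weight cancels in scaled units)."""
    months = meta.age_months
    v_b = BLOOD_VOLUME_INFANT if months <= 3 else BLOOD_VOLUME_OLDER
    f_lo, f_hi = UNSTRESSED_FRACTION
    iex_cap = MAX_VOLUME_RATE_PER_HOUR * v_b / (3600.0 * C_MIN)

    lo = {}
    hi = {}
    lo["p_set"], hi["p_set"] = _bracket(_P_SET_BRACKETS, months)
    lo["hr_min"], hi["hr_min"] = _bracket(_HR_MIN_BRACKETS, months)
    lo["hr_max"], hi["hr_max"] = _bracket(_HR_MAX_BRACKETS, months)
    lo["cv_rel"], hi["cv_rel"] = 10.0, 40.0
    lo["dvv0_rel"], hi["dvv0_rel"] = f_lo * v_b / C_MAX, f_hi * v_b / C_MIN
    lo["iex_rel"], hi["iex_rel"] = -iex_cap, iex_cap
    lo["r_min_scaled"], hi["r_min_scaled"] = 0.1, 2.5
    lo["r_max_scaled"], hi["r_max_scaled"] = 0.25, 3.0
    lo["k_min_rel"], hi["k_min_rel"] = 2.0 / C_MAX, 30.0 / C_MIN
    lo["k_max_rel"], hi["k_max_rel"] = 50.0 / C_MAX, 200.0 / C_MIN
    lo["s_const"], hi["s_const"] = 0.0, 1.0
    lo["s_slope"], hi["s_slope"] = -1.0 / 300.0, 1.0 / 300.0
    lo["m_const"], hi["m_const"] = -1.0, 1.0
    lo["m_slope"], hi["m_slope"] = -1.0 / 150.0, 1.0 / 150.0
    lo["alpha_rc"], hi["alpha_rc"] = 0.1, 10.0
    return ParameterBounds(lo, hi)


def update_bounds_from_observables(bounds: ParameterBounds,
                                   obs: ObservableSeries) -> ParameterBounds:
    """Tighten extremal-parameter bounds using observed data.

    The minimal heart rate cannot exceed the smallest heart rate actually
    observed, nor the maximal fall below the largest; the analogous rule
    applies to the scaled resistance extremes via the RC observable.
    Bounds only ever tighten; a tightening that would empty an interval is
    relaxed to a one-unit interval around the observed extremum.
    """
    new = bounds.copy()
    updates = (
        ("hr_min", "hi", float(np.min(obs.hr)), min),
        ("hr_max", "lo", float(np.max(obs.hr)), max),
        ("r_min_scaled", "hi", float(np.min(obs.rc)), min),
        ("r_max_scaled", "lo", float(np.max(obs.rc)), max),
    )
    unit = {"hr_min": 1.0, "hr_max": 1.0,
            "r_min_scaled": 0.05, "r_max_scaled": 0.05}
    for name, side, observed, combine in updates:
        if side == "hi":
            cand = combine(new.hi[name], observed)
            if cand <= new.lo[name]:
                warnings.warn(
                    f"observed extremum empties {name} interval; widening",
                    stacklevel=2)
                new.lo[name] = observed - unit[name]
                new.hi[name] = observed
            else:
                new.hi[name] = cand
        else:
            cand = combine(new.lo[name], observed)
            if cand >= new.hi[name]:
                warnings.warn(
                    f"observed extremum empties {name} interval; widening",
                    stacklevel=2)
                new.hi[name] = observed + unit[name]
                new.lo[name] = observed
            else:
                new.lo[name] = cand
    return new
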