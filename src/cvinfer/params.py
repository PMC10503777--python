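"""Parameter containers for the cardiovascular model.

The model describes a closed-loop circulation with one pumping chamber, a
compliant arterial compartment, a compliant venous compartment and a lumped
peripheral resistance, under autonomic (baroreflex + independent drive) and
non-autonomic control.  Two parameterizations coexist:

* :class:`ModelParameters` — the fifteen *scaled* quantities the estimator
  infers from data.  Compliances, resistances and contractility only appear
  through ratios with the arterial compliance ``C_a`` (which is itself not
  identifiable from pressures alone).
* :class:`PhysicalParameters` — the physical quantities used when running
  forward simulations, where ``C_a``, ``C_v`` etc. are given in ml/mmHg.

Scaled forms: ``C̃v = Cv/Ca``, ``ΔṼv0 = ΔVv0/Ca`` (mmHg), ``Ĩex = Iex/Ca``
(mmHg/s), ``R̃ = α_RC·Ca·R`` (s), and the relative contractility ``K̃``
(mmHg) which never decomposes into its physical factors.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: Baroreflex gain, 1/mmHg.  Fixed constant, not estimated.
K_B = 0.1838

#: Steepness of the shared autonomic/resistance sigmoids (dimensionless).
SIGMOID_GAIN = 3.3

#: Canonical ordering of the 15 estimated parameters.
PARAM_NAMES = (
    "p_set",
    "cv_rel",
    "dvv0_rel",
    "iex_rel",
    "hr_min",
    "hr_max",
    "r_min_scaled",
    "r_max_scaled",
    "k_min_rel",
    "k_max_rel",
    "s_const",
    "s_slope",
    "m_const",
    "m_slope",
    "alpha_rc",
)


@dataclass(frozen=True)
class PatientMeta:
    """Patient metadata used to select parameter search ranges.

    Parameters
    ----------
    age_years : float
        Age in years (fractions allowed; only the age bracket matters).
    weight_kg : float
        Body weight in kg.
    """

    age_years: float
    weight_kg: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.age_years) or self.age_years < 0:
            raise ValueError(f"age_years must be >= 0, got {self.age_years}")
        if not np.isfinite(self.weight_kg) or self.weight_kg <= 0:
            raise ValueError(f"weight_kg must be > 0, got {self.weight_kg}")

    @property
    def age_months(self) -> float:
        return self.age_years * 12.0


@dataclass(frozen=True)
class ModelParameters:
    """The fifteen scaled hidden parameters.

    Units: pressures mmHg, heart rates beats/min, scaled resistances s,
    slopes 1/s; ``cv_rel``, ``s_const``, ``m_const``, ``alpha_rc``
    dimensionless.
    """

    p_set: float          # baroreflex set point, mmHg
    cv_rel: float         # Cv / Ca
    dvv0_rel: float       # ΔVv0 / Ca, mmHg
    iex_rel: float        # Iex / Ca, mmHg/s (signed)
    hr_min: float         # beats/min
    hr_max: float         # beats/min
    r_min_scaled: float   # α_RC·Ca·R_min, s
    r_max_scaled: float   # α_RC·Ca·R_max, s
    k_min_rel: float      # minimal relative contractility, mmHg
    k_max_rel: float      # maximal relative contractility, mmHg
    s_const: float        # independent autonomic drive at segment start
    s_slope: float        # 1/s
    m_const: float        # non-autonomic SVR modulation at segment start
    m_slope: float        # 1/s
    alpha_rc: float       # pulse-contour scale factor
    k_b: float = K_B      # baroreflex gain, 1/mmHg (fixed)

    def __post_init__(self) -> None:
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError("all parameters must be finite")
        if not self.hr_min < self.hr_max:
            raise ValueError("hr_min must be < hr_max")
        if not self.r_min_scaled < self.r_max_scaled:
            raise ValueError("r_min_scaled must be < r_max_scaled")
        if not self.k_min_rel < self.k_max_rel:
            raise ValueError("k_min_rel must be < k_max_rel")
        if not 0.0 <= self.s_const <= 1.0:
            raise ValueError("s_const must lie in [0, 1]")
        if not -1.0 <= self.m_const <= 1.0:
            raise ValueError("m_const must lie in [-1, 1]")
        for name in ("cv_rel", "dvv0_rel", "r_min_scaled", "k_min_rel",
                     "alpha_rc", "k_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def as_array(self) -> np.ndarray:
        """The 15 estimated parameters in canonical order (k_b excluded)."""
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, theta: np.ndarray, k_b: float = K_B) -> "ModelParameters":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected {len(PARAM_NAMES)} parameters")
        return cls(**dict(zip(PARAM_NAMES, theta)), k_b=k_b)

    def replace(self, **kw) -> "ModelParameters":
        return replace(self, **kw)


@dataclass(frozen=True)
class PhysicalParameters:
    """Physical (unscaled) parameters for forward simulation.

    Contractility is kept in its relative form ``K̃`` (mmHg) because its
    physical factors never appear separately in the pressure equations.
    """

    c_a: float            # arterial compliance, ml/mmHg
    c_v: float            # venous compliance, ml/mmHg
    dv_v0: float          # unstressed venous volume span, ml
    r_min: float          # mmHg·s/ml
    r_max: float          # mmHg·s/ml
    p_set: float          # mmHg
    hr_min: float         # beats/min
    hr_max: float         # beats/min
    k_min_rel: float      # mmHg
    k_max_rel: float      # mmHg
    i_ex: float = 0.0     # baseline volume current, ml/s (signed)
    s_const: float = 0.2
    s_slope: float = 0.0
    m_const: float = 0.0
    m_slope: float = 0.0
    alpha_rc: float = 1.0
    k_b: float = K_B

    def __post_init__(self) -> None:
        for name in ("c_a", "c_v", "dv_v0", "r_min", "k_min_rel", "alpha_rc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not self.hr_min < self.hr_max:
            raise ValueError("hr_min must be < hr_max")
        if not self.r_min < self.r_max:
            raise ValueError("r_min must be < r_max")
        if not self.k_min_rel < self.k_max_rel:
            raise ValueError("k_min_rel must be < k_max_rel")

    def to_scaled(self) -> ModelParameters:
        """Convert to the scaled parameterization the estimator works in."""
        return ModelParameters(
            p_set=self.p_set,
            cv_rel=self.c_v / self.c_a,
            dvv0_rel=self.dv_v0 / self.c_a,
            iex_rel=self.i_ex / self.c_a,
            hr_min=self.hr_min,
            hr_max=self.hr_max,
            r_min_scaled=self.alpha_rc * self.c_a * self.r_min,
            r_max_scaled=self.alpha_rc * self.c_a * self.r_max,
            k_min_rel=self.k_min_rel,
            k_max_rel=self.k_max_rel,
            s_const=self.s_const,
            s_slope=self.s_slope,
            m_const=self.m_const,
            m_slope=self.m_slope,
            alpha_rc=self.alpha_rc,
            k_b=self.k_b,
        )


#: Printed reference parameter set used throughout the forward simulations
#: (a neonate-like artificial patient).
SIMULATION_REFERENCE = PhysicalParameters(
    c_a=0.45,
    c_v=10.0,
    dv_v0=65.0,
    r_min=0.8,
    r_max=1.8,
    p_set=50.0,
    hr_min=100.0,
    hr_max=180.0,
    k_min_rel=200.0,
    k_max_rel=800.0,
    s_const=0.2,
)
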