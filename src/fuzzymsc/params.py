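"""The model parameter set.

Twenty parameters are flagged free by default and carry uniform priors for
calibration; the remaining entries (cell-cycle bias shape, observable
scale constants) are structural defaults. Units: concentrations in mM
(Mg2+) or ng/mL (growth factors), rates and chances per hour (one
simulation step), maturity and controller outputs dimensionless in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

__all__ = ["ParameterSet", "Prior", "FREE_PARAMETERS", "default_priors"]

#: The free parameters, in canonical order.
FREE_PARAMETERS = (
    "gamma_p0",   # base proliferation chance per step
    "gamma_m0",   # base mortality chance per step
    "alpha_p",    # proliferation scale factor
    "alpha_m",    # mortality scale factor
    "alpha_pm",   # mitotic-damage weight on mortality
    "alpha_d",    # differentiation scale factor
    "r_d0",       # base differentiation rate per step
    "m_t",        # maturity threshold splitting early/late phases
    "gamma_c",    # initial DNA-damage chance (cell passaging)
    "ph_t",       # ambient pH causing DNA damage after one hour
    "r_r",        # internal-pH recovery rate (pH units / h)
    "a_t",        # alkalinity gap where the severe level peaks
    "cmlt",       # Mg membership peak: stimulatory (mM)
    "cmmt",       # Mg membership peak: high (mM)
    "cmht",       # Mg membership peak: destructive (mM)
    "cclt1",      # density membership breakpoints
    "cclt2",
    "ccht1",
    "ccht2",
    "wc",         # cellular consumption weight for growth factors (/h)
)


@dataclass(frozen=True)
class Prior:
    """Uniform prior of one free parameter."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"{self.name}: prior needs lo < hi")

    @property
    def range(self) -> float:
        return self.hi - self.lo


@dataclass(frozen=True)
class ParameterSet:
    """All model parameters with culture-scale defaults.

    Defaults describe an unstimulated monolayer culture: divisions roughly
    every 30-40 h once the cycle-time gate opens, a few-percent mortality
    per day, and full osteoblastic maturation over about three weeks of
    sustained commitment.
    """

    # stochastic event equations
    gamma_p0: float = 0.10
    gamma_m0: float = 0.002
    alpha_p: float = 2.0
    alpha_m: float = 2.0
    alpha_pm: float = 1.0
    alpha_d: float = 2.0
    r_d0: float = 0.002
    m_t: float = 0.5
    # DNA damage and alkalinity
    gamma_c: float = 0.05
    ph_t: float = 9.0
    r_r: float = 0.02
    a_t: float = 0.8
    # membership breakpoints
    cmlt: float = 4.5
    cmmt: float = 15.0
    cmht: float = 30.0
    cclt1: float = 0.10
    cclt2: float = 0.25
    ccht1: float = 0.60
    ccht2: float = 0.85
    # growth-factor coupling
    wc: float = 0.005
    # fixed-by-default extras
    k_omega: float = 0.4      # logistic growth rate of the cycle bias (/h)
    t_cyc: float = 26.0       # mean cell-cycle time (h)
    delta_p_persistence: float = 26.0  # hours the mitotic-damage flag lasts
    kappa_dna: float = 1.0    # DNA content per live cell (a.u.)
    kappa_alp: float = 1.0    # ALP activity scale (a.u.)
    kappa_oc: float = 1.0     # OC content scale (a.u.)

    def __post_init__(self) -> None:
        for name in ("gamma_p0", "gamma_m0", "alpha_p", "alpha_m", "alpha_pm",
                     "alpha_d", "r_d0", "gamma_c", "r_r", "wc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 < self.m_t < 1:
            raise ValueError("m_t must lie in (0, 1)")
        if not self.cmlt < self.cmmt < self.cmht:
            raise ValueError("Mg membership peaks must satisfy cmlt < cmmt < cmht")
        if not (self.cclt1 < self.cclt2 <= self.ccht1 < self.ccht2):
            raise ValueError("density breakpoints must satisfy cclt1 < cclt2 <= ccht1 < ccht2")

    def replace(self, **kwargs) -> "ParameterSet":
        return replace(self, **kwargs)

    def with_values(self, values: dict[str, float]) -> "ParameterSet":
        return replace(self, **values)

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @property
    def free_values(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FREE_PARAMETERS}


def default_priors(base: ParameterSet | None = None) -> dict[str, Prior]:
    """Uniform priors spanning the plausible range of each free parameter.

    Multiplicative parameters get a [0.5x, 2x] band around the default;
    thresholds and breakpoints get additive bands that preserve their
    ordering constraints.
    """
    p = base or ParameterSet()
    bands: dict[str, tuple[float, float]] = {
        "gamma_p0": (0.5 * p.gamma_p0, 2.0 * p.gamma_p0),
        "gamma_m0": (0.5 * p.gamma_m0, 2.0 * p.gamma_m0),
        "alpha_p": (0.5 * p.alpha_p, 2.0 * p.alpha_p),
        "alpha_m": (0.5 * p.alpha_m, 2.0 * p.alpha_m),
        "alpha_pm": (0.5 * p.alpha_pm, 2.0 * p.alpha_pm),
        "alpha_d": (0.5 * p.alpha_d, 2.0 * p.alpha_d),
        "r_d0": (0.5 * p.r_d0, 2.0 * p.r_d0),
        "m_t": (0.3, 0.7),
        "gamma_c": (0.0, 0.2),
        "ph_t": (8.5, 9.5),
        "r_r": (0.5 * p.r_r, 2.0 * p.r_r),
        "a_t": (0.5, 1.2),
        "cmlt": (3.0, 8.0),
        "cmmt": (10.0, 18.0),
        "cmht": (20.0, 40.0),
        "cclt1": (0.05, 0.15),
        "cclt2": (0.18, 0.35),
        "ccht1": (0.45, 0.70),
        "ccht2": (0.75, 0.95),
        "wc": (0.5 * p.wc, 2.0 * p.wc),
    }
    return {name: Prior(name, *bands[name]) for name in FREE_PARAMETERS}
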