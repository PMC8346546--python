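"""Culture microenvironment: growth-factor fields, Mg2+ and pH.

TGF-beta1 and BMP2 live on the lattice as concentration fields (ng/mL)
driven by cellular production, cellular consumption, first-order
degradation and explicit finite-difference diffusion with no-flux walls.
Mg2+ and ambient pH are spatially uniform (a well-mixed medium: ions
equilibrate much faster than proteins). Dissolved Mg2+ raises the medium
pH through an affine map, and every 2.5 days a medium change resets the
growth factors, pH and Mg2+ to their fresh-medium values for protocols
longer than 3 days.

Cells producing growth factors do so maturity-dependently: committed cells
in their early differentiation phase secrete at the full rate, late-phase
cells at a configurable fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GrowthFactorField", "EnvironmentState", "PhModel", "diffuse", "MEDIUM_CHANGE_INTERVAL_H"]

MEDIUM_CHANGE_INTERVAL_H = 60.0  # 2.5 days
MEDIUM_CHANGE_MIN_DURATION_H = 72.0  # no change for protocols of 3 days or less


def diffuse(conc: np.ndarray, diffusivity: float, dt: float, h: float) -> np.ndarray:
    """One explicit diffusion step with no-flux boundaries.

    Substeps automatically whenever the 3D stability bound
    ``D dt / h^2 <= 1/6`` would be violated. Mass is conserved exactly up
    to floating-point rounding.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if diffusivity < 0:
        raise ValueError("diffusivity must be non-negative")
    if diffusivity == 0.0:
        return conc.copy()
    r = diffusivity * dt / h**2
    n_sub = max(1, int(np.ceil(r / (1.0 / 6.0))))
    tau = r / n_sub
    c = conc.astype(float, copy=True)
    for _ in range(n_sub):
        padded = np.pad(c, 1, mode="edge")  # zero-gradient walls
        lap = (
            padded[2:, 1:-1, 1:-1] + padded[:-2, 1:-1, 1:-1]
            + padded[1:-1, 2:, 1:-1] + padded[1:-1, :-2, 1:-1]
            + padded[1:-1, 1:-1, 2:] + padded[1:-1, 1:-1, :-2]
            - 6.0 * c
        )
        c = c + tau * lap
    return c


@dataclass
class GrowthFactorField:
    """One diffusible factor on the lattice.

    Rates: ``production`` in ng/mL per hour added to a producing cell's
    patch, ``degradation`` per hour, ``diffusivity`` in um^2/h,
    ``late_production_factor`` scaling secretion of late-phase cells.
    Consumption is first-order in the local concentration with the
    cellular weight ``wc`` (/h) supplied per reaction step.
    """

    name: str
    shape: tuple[int, int, int]
    initial: float = 0.0
    diffusivity: float = 100.0
    degradation: float = 0.01
    production: float = 5e-4
    late_production_factor: float = 0.5
    patch_size_um: float = 15.0
    conc: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.conc = np.full(self.shape, float(self.initial))

    def reset(self) -> None:
        self.conc = np.full(self.shape, float(self.initial))

    def diffuse(self, dt: float) -> None:
        self.conc = diffuse(self.conc, self.diffusivity, dt, self.patch_size_um)

    def react(self, cell_mask: np.ndarray, early_mask: np.ndarray, wc: float, dt: float) -> None:
        """Apply production, consumption and degradation for one step.

        ``cell_mask`` flags occupied patches, ``early_mask`` the subset
        whose occupant is in the early differentiation phase.
        """
        if dt <= 0:
            raise ValueError("dt must be positive")
        prod = self.production * np.where(early_mask, 1.0, self.late_production_factor)
        self.conc = self.conc + np.where(cell_mask, prod, 0.0) * dt
        self.conc = self.conc - np.where(cell_mask, wc * self.conc, 0.0) * dt
        self.conc = self.conc - self.degradation * self.conc * dt
        np.maximum(self.conc, 0.0, out=self.conc)

    def save_layers(self, directory, prefix: str | None = None) -> list:
        """Write one dense CSV matrix per z-layer for visualisation."""
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        prefix = prefix or self.name
        paths = []
        for z in range(self.shape[2]):
            path = directory / f"{prefix}_z{z}.csv"
            np.savetxt(path, self.conc[:, :, z], delimiter=",")
            paths.append(path)
        return paths

    @property
    def total_mass(self) -> float:
        return float(self.conc.sum())

    @property
    def mean_concentration(self) -> float:
        return float(self.conc.mean())


@dataclass(frozen=True)
class PhModel:
    """Affine Mg2+ -> medium pH map with a physiological ceiling.

    ``ph = ph0 + slope * (mg - mg0)`` clamped to ``ceiling``; ``mg0`` is
    the 0.8 mM Mg2+ background of standard culture medium at ``ph0``.
    """

    ph0: float = 7.4
    slope: float = 0.02
    mg0: float = 0.8
    ceiling: float = 10.0

    def __call__(self, mg_mM: float) -> float:
        if mg_mM < 0:
            raise ValueError("Mg concentration must be non-negative")
        return min(self.ph0 + self.slope * (mg_mM - self.mg0), self.ceiling)


@dataclass
class EnvironmentState:
    """Uniform Mg2+/pH plus the spatial growth-factor fields."""

    mg_mM: float
    shape: tuple[int, int, int]
    ph_model: PhModel = field(default_factory=PhModel)
    fields: dict[str, GrowthFactorField] = field(default_factory=dict)
    medium_change_interval_h: float = MEDIUM_CHANGE_INTERVAL_H
    duration_h: float = float("inf")
    ambient_ph: float = field(init=False)

    def __post_init__(self) -> None:
        if self.mg_mM < 0:
            raise ValueError("Mg concentration must be non-negative")
        self.initial_mg = float(self.mg_mM)
        self.ambient_ph = self.ph_model(self.mg_mM)
        if not self.fields:
            self.fields = {
                "tgfb1": GrowthFactorField("tgfb1", self.shape),
                "bmp2": GrowthFactorField("bmp2", self.shape, production=2.5e-4),
            }

    def medium_change_due(self, t_h: float) -> bool:
        """True when a fresh-medium reset falls on hour ``t_h``.

        Media are only exchanged in protocols longer than 3 days.
        """
        if self.duration_h <= MEDIUM_CHANGE_MIN_DURATION_H:
            return False
        if t_h <= 0:
            return False
        k = t_h / self.medium_change_interval_h
        return abs(k - round(k)) < 1e-9

    def medium_change(self) -> None:
        """Reset growth factors, pH and Mg2+ to fresh-medium values."""
        for f in self.fields.values():
            f.reset()
        self.mg_mM = self.initial_mg
        self.ambient_ph = self.ph_model(self.mg_mM)

    def react_and_diffuse(self, cell_mask: np.ndarray, early_mask: np.ndarray,
                          wc: float, dt: float) -> None:
        for f in self.fields.values():
            f.react(cell_mask, early_mask, wc, dt)
            f.diffuse(dt)
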