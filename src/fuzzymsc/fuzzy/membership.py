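"""Piecewise-linear membership functions and linguistic inputs.

Every cellular input to the decision controller (Mg2+ concentration,
alkalinity, BMP2, TGF-beta1, cell density, maturity, DNA damage) is
described by an ordered family of linguistic levels, each level carrying a
piecewise-linear membership function: triangles, trapezoids and shoulder
functions expressed as (x, y) breakpoint lists. Outside the breakpoint
range a function holds its boundary value, which is how shoulders saturate
at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MembershipFunction", "LinguisticInput"]


@dataclass(frozen=True)
class MembershipFunction:
    """One linguistic level of an input variable.

    Parameters
    ----------
    name
        Level label, e.g. ``"stimulatory"``.
    points
        Breakpoints as ``((x0, y0), (x1, y1), ...)`` with strictly
        increasing ``x`` and ``y`` in [0, 1]. Membership is linearly
        interpolated between breakpoints and clamped to the first/last
        ``y`` outside their range.
    """

    name: str
    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        xs = np.asarray([p[0] for p in self.points], dtype=float)
        ys = np.asarray([p[1] for p in self.points], dtype=float)
        if xs.size < 2:
            raise ValueError(f"{self.name}: need at least two breakpoints")
        if not np.all(np.diff(xs) > 0):
            raise ValueError(f"{self.name}: breakpoint abscissae must increase")
        if ys.min() < 0 or ys.max() > 1:
            raise ValueError(f"{self.name}: membership values must lie in [0, 1]")

    @property
    def xs(self) -> np.ndarray:
        return np.asarray([p[0] for p in self.points], dtype=float)

    @property
    def ys(self) -> np.ndarray:
        return np.asarray([p[1] for p in self.points], dtype=float)

    def __call__(self, x):
        """Membership degree at ``x`` (scalar or array)."""
        return np.interp(x, self.xs, self.ys)

    @staticmethod
    def triangle(name: str, a: float, b: float, c: float) -> "MembershipFunction":
        return MembershipFunction(name, ((a, 0.0), (b, 1.0), (c, 0.0)))

    @staticmethod
    def trapezoid(name: str, a: float, b: float, c: float, d: float) -> "MembershipFunction":
        return MembershipFunction(name, ((a, 0.0), (b, 1.0), (c, 1.0), (d, 0.0)))

    @staticmethod
    def shoulder_left(name: str, a: float, b: float) -> "MembershipFunction":
        """Full membership below ``a``, falling to zero at ``b``."""
        return MembershipFunction(name, ((a, 1.0), (b, 0.0)))

    @staticmethod
    def shoulder_right(name: str, a: float, b: float) -> "MembershipFunction":
        """Zero membership below ``a``, saturating at one beyond ``b``."""
        return MembershipFunction(name, ((a, 0.0), (b, 1.0)))

    def to_dict(self) -> dict:
        return {"name": self.name, "points": [[float(x), float(y)] for x, y in self.points]}

    @staticmethod
    def from_dict(d: dict) -> "MembershipFunction":
        return MembershipFunction(d["name"], tuple((float(x), float(y)) for x, y in d["points"]))


@dataclass
class LinguisticInput:
    """An input variable with its ordered linguistic levels.

    ``crisp`` inputs (DNA damage) bypass interpolation: the crisp value 0
    activates the first level and 1 the second, each at degree exactly 1.
    """

    name: str
    levels: list[MembershipFunction] = field(default_factory=list)
    crisp: bool = False
    nonnegative: bool = True

    def __post_init__(self) -> None:
        if self.crisp and len(self.levels) != 2:
            raise ValueError(f"{self.name}: crisp inputs need exactly two levels")

    @property
    def level_names(self) -> list[str]:
        return [m.name for m in self.levels]

    def fuzzify(self, x: float) -> dict[str, float]:
        """Map a crisp value to a level -> degree dictionary."""
        degrees = self.fuzzify_batch(np.asarray([x], dtype=float))[0]
        return dict(zip(self.level_names, (float(d) for d in degrees)))

    def fuzzify_batch(self, x: np.ndarray) -> np.ndarray:
        """Vectorised fuzzification: (n,) values -> (n, n_levels) degrees."""
        x = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError(f"{self.name}: non-finite input value")
        if self.nonnegative and np.any(x < 0):
            raise ValueError(f"{self.name}: negative value outside domain")
        if self.crisp:
            bad = ~np.isin(x, (0.0, 1.0))
            if np.any(bad):
                raise ValueError(f"{self.name}: crisp input must be 0 or 1")
            out = np.zeros((x.size, 2))
            out[:, 0] = x == 0.0
            out[:, 1] = x == 1.0
            return out
        out = np.empty((x.size, len(self.levels)))
        for j, mf in enumerate(self.levels):
            out[:, j] = mf(x)
        return out

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "crisp": self.crisp,
            "nonnegative": self.nonnegative,
            "levels": [m.to_dict() for m in self.levels],
        }

    @staticmethod
    def from_dict(d: dict) -> "LinguisticInput":
        return LinguisticInput(
            name=d["name"],
            levels=[MembershipFunction.from_dict(m) for m in d["levels"]],
            crisp=bool(d.get("crisp", False)),
            nonnegative=bool(d.get("nonnegative", True)),
        )
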