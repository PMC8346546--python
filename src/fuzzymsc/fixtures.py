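"""Synthetic cell-culture studies for download-free testing and recovery.

Three study templates mirror the measurement schedules of the cell-culture
experiments the model targets:

``study1``
    five Mg2+ conditions (0.8, 3, 6, 12, 60 mM), live cell count and
    viability after 3 days;
``study2``
    two conditions (0.78 control, 5 mM), differentiation markers ALP and
    OC, DNA content and the growth factors TGF-beta1/BMP2 at days 7, 14
    and 21;
``study3``
    four conditions (0.8, 3, 6, 14 mM), live cell count at days 3, 6
    and 9.

:func:`generate` runs the simulator at a known ground-truth parameter set,
applies Gaussian relative observation noise, and returns the measurement
table together with the truth record so calibration runs can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import ObservedDataset
from .fuzzy import default_controller
from .params import ParameterSet, Prior
from .simulation import ExperimentProtocol, run

__all__ = ["SyntheticStudy", "study_protocols", "generate", "make_simulator", "recovery_priors"]

STUDY_CONDITIONS = {
    "study1": (0.8, 3.0, 6.0, 12.0, 60.0),
    "study2": (0.78, 5.0),
    "study3": (0.8, 3.0, 6.0, 14.0),
}


def study_protocols(template: str, world_shape: tuple[int, int, int] = (30, 30, 8),
                    seed_count: int = 200, conditions: tuple[float, ...] | None = None
                    ) -> list[ExperimentProtocol]:
    """The per-condition protocols of one study template."""
    if template not in STUDY_CONDITIONS:
        raise ValueError(f"unknown template {template!r}")
    conditions = conditions or STUDY_CONDITIONS[template]
    if template == "study1":
        duration, schedule = 3.0, ((3.0, ("live_count", "viability")),)
    elif template == "study2":
        duration = 21.0
        markers = ("dna", "alp", "oc", "tgfb1", "bmp2")
        schedule = tuple((day, markers) for day in (7.0, 14.0, 21.0))
    else:
        duration, schedule = 9.0, tuple((day, ("live_count",)) for day in (3.0, 6.0, 9.0))
    return [
        ExperimentProtocol(
            mg_mM=mg, seed_count=seed_count, duration_days=duration,
            schedule=schedule, world_shape=world_shape,
        )
        for mg in conditions
    ]


@dataclass(frozen=True)
class SyntheticStudy:
    """A generated dataset together with its generating truth."""

    template: str
    dataset: ObservedDataset
    truth: ParameterSet
    noise: float
    seed: int


def generate(template: str, truth: ParameterSet | None = None, noise: float = 0.15,
             seed: int = 0, replicates: int = 1, min_viability: float | None = None,
             **protocol_kwargs) -> SyntheticStudy:
    """Emit a study-shaped measurement table from a ground-truth run.

    ``noise`` is the relative sd of the Gaussian observation noise applied
    to every measured mean (0 reproduces the simulator output exactly);
    the reported sd column is ``noise`` times the absolute mean.
    """
    if noise < 0:
        raise ValueError("noise must be non-negative")
    truth = truth or ParameterSet()
    protocols = study_protocols(template, **protocol_kwargs)
    summary, _ = run(protocols, params=truth, seed=seed, replicates=replicates,
                     controller=default_controller(truth))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2**20]))
    noisy = summary.copy()
    noisy["sd"] = noise * noisy["mean"].abs()
    noisy["mean"] = noisy["mean"] * (1.0 + noise * rng.standard_normal(len(noisy)))
    dataset = ObservedDataset(noisy[["condition", "day", "observable", "mean", "sd"]],
                              min_viability=min_viability)
    return SyntheticStudy(template, dataset, truth, noise, seed)


def make_simulator(protocols, base: ParameterSet | None = None,
                   measure_viability: bool = False):
    """A ``simulate(values, seed)`` closure for the calibration engine.

    ``values`` overrides entries of the base parameter set; the controller
    is rebuilt per call because membership breakpoints are themselves free
    parameters. With ``measure_viability`` the returned tables always
    include viability rows so datasets can impose a minimum-viability
    constraint.
    """
    base = base or ParameterSet()
    if measure_viability:
        protocols = [
            ExperimentProtocol(
                mg_mM=p.mg_mM, seed_count=p.seed_count, duration_days=p.duration_days,
                schedule=tuple(
                    (day, obs if "viability" in obs else obs + ("viability",))
                    for day, obs in p.schedule
                ),
                world_shape=p.world_shape, medium_change=p.medium_change,
                normalize_gf_by_dna=p.normalize_gf_by_dna,
            )
            for p in protocols
        ]

    def simulate(values: dict[str, float], seed: int):
        params = base.with_values(values)
        summary, _ = run(protocols, params=params, seed=seed, replicates=1,
                         controller=default_controller(params))
        return summary.rename(columns={"mean": "value"})[["condition", "day", "observable", "value"]]

    return simulate


def recovery_priors(truth: ParameterSet, names: tuple[str, ...],
                    lo_factor: float = 0.5, hi_factor: float = 2.0) -> dict[str, Prior]:
    """Uniform priors bracketing the truth by multiplicative factors.

    The default factor-of-two band mimics a calibration where each rate is
    known to order of magnitude but not precisely; the truth sits off the
    band centre, as it would in practice.
    """
    return {
        name: Prior(name, lo_factor * getattr(truth, name), hi_factor * getattr(truth, name))
        for name in names
    }
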