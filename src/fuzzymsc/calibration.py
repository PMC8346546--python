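"""Iterative calibration: sensitivity screening plus rejection ABC.

The model has 20 free parameters; sampling a 20-dimensional prior densely
enough for approximate Bayesian computation is impractical, so calibration
proceeds iteratively. Each round

1. screens the current free parameters with a two-level fractional
   factorial design (a fold-over of a Hadamard design, resolution IV, so
   main effects are unconfounded with two-way interactions) and ranks them
   by ANOVA main-effect F statistics of the fit metric,
2. runs rejection ABC on the top five parameters: sample parameter sets
   from the priors, simulate, score each by the distance 1 - R2, and keep
   the best ``n_keep`` as the posterior sample,
3. accepts the posterior median of every parameter whose posterior is
   significantly narrower than its prior (interquartile range below
   ``rho`` times the prior's uniform IQR), returning the rest to the free
   pool,

and terminates once an iteration accepts nothing (or a round limit is
reached). The fit metric R2 is the normalised absolute difference
``1 - sum|sim - obs| / sum|obs|`` per observable, averaged over
observables. Datasets without viability measurements may declare a
minimum viability; parameter sets whose simulated viability drops below
it receive the worst possible distance.

The engine is simulator-agnostic: any callable ``simulate(values, seed)``
returning a tidy (condition, day, observable, value) table can be
calibrated, which is also how the test-suite cross-checks the machinery
against cheap closed-form surrogates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.linalg import hadamard

from .params import Prior

__all__ = [
    "ObservedDataset",
    "CalibrationConfig",
    "CalibrationState",
    "r_squared",
    "ffd_design",
    "ffd_screen",
    "select_top",
    "abc_reject",
    "narrowing_test",
    "iterate",
]

KEYS = ["condition", "day", "observable"]


@dataclass
class ObservedDataset:
    """Measurement table plus the optional minimum-viability constraint."""

    table: pd.DataFrame  # columns: condition, day, observable, mean, sd
    min_viability: float | None = None

    def __post_init__(self) -> None:
        required = set(KEYS + ["mean"])
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"dataset lacks columns {sorted(missing)}")
        if "sd" in self.table.columns and (self.table["sd"] < 0).any():
            raise ValueError("sd must be non-negative")


def r_squared(simulated: pd.DataFrame, observed: pd.DataFrame) -> float:
    """Goodness of fit as the normalised absolute difference.

    Per observable ``R2 = 1 - sum|sim - obs| / sum|obs|`` over the matched
    (condition, day) points, then averaged across observables. A perfect
    match gives 1; predicting zero everywhere gives 0.
    """
    obs = observed.rename(columns={"mean": "obs"})[KEYS + ["obs"]]
    sim = simulated.rename(columns={"value": "sim", "mean": "sim"})[KEYS + ["sim"]]
    merged = obs.merge(sim, on=KEYS, how="left")
    if merged["sim"].isna().any():
        missing = merged.loc[merged["sim"].isna(), KEYS]
        raise ValueError(f"simulation lacks observed keys:\n{missing}")
    scores = []
    for _, g in merged.groupby("observable"):
        denom = g["obs"].abs().sum()
        if denom == 0:
            scores.append(1.0 if np.allclose(g["sim"], 0.0) else 0.0)
        else:
            scores.append(1.0 - (g["sim"] - g["obs"]).abs().sum() / denom)
    return float(np.mean(scores))


# -- sensitivity screening -------------------------------------------------

def ffd_design(n_params: int) -> np.ndarray:
    """Two-level fold-over Hadamard design, +-1 coded, resolution IV.

    Rows are runs, columns parameters; the fold-over (appending the
    negated design) de-aliases main effects from two-way interactions.
    """
    if n_params < 1:
        raise ValueError("need at least one parameter")
    size = 2
    while size < n_params + 1:
        size *= 2
    h = hadamard(size)[:, 1:n_params + 1]
    return np.vstack([h, -h]).astype(float)


def _anova_main_effects(design: np.ndarray, y: np.ndarray, names: list[str]) -> pd.Series:
    """Main-effect F statistics of an orthogonal 2-level design."""
    n, p = design.shape
    y = np.asarray(y, dtype=float)
    effects = design.T @ y / (n / 2)  # mean(+) - mean(-) per column
    ss = n / 4.0 * effects**2
    sst = float(((y - y.mean()) ** 2).sum())
    sse = max(sst - ss.sum(), 0.0)
    dfe = n - p - 1
    if dfe > 0 and sse > 1e-9 * max(sst, 1e-300):
        stats = ss / (sse / dfe)
    else:  # saturated design or (numerically) perfect fit: rank by |effect|
        stats = np.abs(effects)
    return pd.Series(stats, index=names)


def ffd_screen(priors: dict[str, Prior], simulate: Callable, data: ObservedDataset,
               seed: int, fixed: dict[str, float] | None = None,
               min_viability: float | None = None) -> pd.Series:
    """Rank free parameters by their main effect on the fit metric.

    Each design row sets every screened parameter to its prior low or high
    bound, runs the simulator, and scores the fit with :func:`r_squared`.
    Returns F statistics scaled so the largest equals 1, sorted
    descending.
    """
    names = sorted(priors)
    if len(names) < 2:
        raise ValueError("screening needs at least two free parameters")
    design = ffd_design(len(names))
    root = np.random.SeedSequence(seed)
    run_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(design.shape[0])]
    y = np.empty(design.shape[0])
    for r, row in enumerate(design):
        values = dict(fixed or {})
        values.update({
            name: (priors[name].hi if sign > 0 else priors[name].lo)
            for name, sign in zip(names, row)
        })
        sim = simulate(values, run_seeds[r])
        y[r] = _score(sim, data, min_viability)
    finite = np.isfinite(y)
    if not finite.all():
        # constraint-violating rows score one fit-range below the worst
        # finite run, keeping them strictly worse but ANOVA-friendly
        if finite.any():
            lo, hi = y[finite].min(), y[finite].max()
            y = np.where(finite, y, lo - max(hi - lo, 1.0))
        else:
            y = np.zeros_like(y)
    stats = _anova_main_effects(design, y, names)
    top = stats.max()
    if top > 0:
        stats = stats / top
    return stats.sort_values(ascending=False, kind="stable")


def select_top(effects: pd.Series, k: int = 5) -> list[str]:
    """The ``k`` largest effects; ties broken by parameter name."""
    if k > len(effects):
        raise ValueError("k exceeds the parameter pool")
    order = sorted(effects.index, key=lambda name: (-effects[name], name))
    return order[:k]


# -- approximate Bayesian computation --------------------------------------

def _score(sim: pd.DataFrame, data: ObservedDataset, min_viability: float | None) -> float:
    """R2 of a simulated table, with the minimum-viability penalty."""
    threshold = min_viability if min_viability is not None else data.min_viability
    if threshold is not None:
        viab = sim.loc[sim["observable"] == "viability", "value" if "value" in sim else "mean"]
        if len(viab) and (viab < threshold).any():
            return -np.inf
    fit_keys = data.table[KEYS].drop_duplicates()
    sim_fit = sim.merge(fit_keys, on=KEYS, how="inner")
    return r_squared(sim_fit, data.table)


def abc_reject(priors: dict[str, Prior], simulate: Callable, data: ObservedDataset,
               n_runs: int, n_keep: int, seed: int,
               fixed: dict[str, float] | None = None) -> pd.DataFrame:
    """Rejection ABC over the selected parameters.

    Samples ``n_runs`` parameter vectors from the uniform priors, runs the
    simulator for each, and keeps the ``n_keep`` sets with the smallest
    distance ``1 - R2``. Returns the posterior sample with its ``distance``
    and ``r2`` columns, best first. A degenerate posterior (every run
    violating the viability constraint) is flagged via the ``degenerate``
    attribute in ``DataFrame.attrs``.
    """
    if n_keep > n_runs:
        raise ValueError("n_keep cannot exceed n_runs")
    names = sorted(priors)
    root = np.random.SeedSequence(seed)
    sampler = np.random.default_rng(root.spawn(1)[0])
    run_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(n_runs + 1)[1:]]
    samples = {
        name: sampler.uniform(priors[name].lo, priors[name].hi, n_runs) for name in names
    }
    r2 = np.empty(n_runs)
    for r in range(n_runs):
        values = dict(fixed or {})
        values.update({name: samples[name][r] for name in names})
        sim = simulate(values, run_seeds[r])
        r2[r] = _score(sim, data, None)
    distance = 1.0 - r2
    order = np.argsort(distance, kind="stable")[:n_keep]
    posterior = pd.DataFrame({name: samples[name][order] for name in names})
    posterior["r2"] = r2[order]
    posterior["distance"] = distance[order]
    posterior.attrs["degenerate"] = bool(np.isinf(distance[order]).all())
    return posterior


def narrowing_test(posterior: np.ndarray | pd.Series, prior: Prior, rho: float = 0.5) -> bool:
    """Accept when the posterior is significantly narrower than the prior.

    A uniform prior on [lo, hi] has IQR 0.5 (hi - lo); accept iff the
    posterior IQR is strictly below ``rho`` times that.
    """
    values = np.asarray(posterior, dtype=float)
    if values.size == 0:
        raise ValueError("empty posterior")
    q75, q25 = np.percentile(values, [75, 25])
    return (q75 - q25) < rho * 0.5 * prior.range


# -- the iterative loop ----------------------------------------------------

@dataclass
class CalibrationConfig:
    n_runs: int = 5000
    n_keep: int = 100
    k_top: int = 5
    rho: float = 0.5
    max_iterations: int = 20
    r2_gain_tolerance: float | None = None  # optional alternative stopping rule


@dataclass
class CalibrationState:
    """Free/fixed partition plus the per-iteration audit trail."""

    free: dict[str, Prior]
    fixed: dict[str, float] = field(default_factory=dict)
    iteration: int = 0
    records: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = set(self.free) & set(self.fixed)
        if overlap:
            raise ValueError(f"parameters both free and fixed: {sorted(overlap)}")


def iterate(state: CalibrationState, simulate: Callable, data: ObservedDataset,
            config: CalibrationConfig | None = None, seed: int = 0) -> CalibrationState:
    """Run the screen -> select -> ABC -> narrowing loop to termination.

    Terminates when an iteration accepts no parameter, the free pool is
    exhausted, ``max_iterations`` is reached, or (when configured) the
    iteration-to-iteration gain in mean R2 of the kept runs falls below
    ``r2_gain_tolerance``.
    """
    config = config or CalibrationConfig()
    root = np.random.SeedSequence(seed)
    while state.free and state.iteration < config.max_iterations:
        it_seed = root.spawn(1)[0]
        screen_seed, abc_seed = (int(s.generate_state(1)[0] % (2**31)) for s in it_seed.spawn(2))
        state.iteration += 1
        if len(state.free) >= 2:
            effects = ffd_screen(state.free, simulate, data, screen_seed, fixed=state.fixed)
            selected = select_top(effects, min(config.k_top, len(state.free)))
        else:
            effects = pd.Series({name: 1.0 for name in state.free})
            selected = list(state.free)
        posterior = abc_reject(
            {name: state.free[name] for name in selected}, simulate, data,
            config.n_runs, config.n_keep, abc_seed, fixed=state.fixed,
        )
        finite = posterior["r2"][np.isfinite(posterior["r2"])]
        accepted: dict[str, float] = {}
        if not posterior.attrs.get("degenerate", False):
            for name in selected:
                if narrowing_test(posterior[name], state.free[name], config.rho):
                    accepted[name] = float(posterior[name].median())
        record = {
            "iteration": state.iteration,
            "effects": effects,
            "posterior": posterior,
            "selected": selected,
            "accepted": dict(accepted),
            "posterior_medians": {name: float(posterior[name].median()) for name in selected},
            "r2_mean": float(finite.mean()) if len(finite) else float("nan"),
            "r2_sd": float(finite.std(ddof=1)) if len(finite) > 1 else 0.0,
            "degenerate": posterior.attrs.get("degenerate", False),
        }
        state.records.append(record)
        for name, value in accepted.items():
            state.fixed[name] = value
            del state.free[name]
        if not accepted:
            break
        if config.r2_gain_tolerance is not None and len(state.records) >= 2:
            gain = state.records[-1]["r2_mean"] - state.records[-2]["r2_mean"]
            if gain < config.r2_gain_tolerance:
                break
    return state
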