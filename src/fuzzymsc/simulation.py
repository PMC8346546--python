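"""Simulation coordinator: hourly iteration of cells and growth factors.

One iteration represents one hour. Each step the engine updates every
cell's internal pH and DNA-damage state, evaluates the fuzzy controller on
the whole population in a single vectorised pass, samples the stochastic
events (mortality, then proliferation, then migration, with cells visited
in random order inside each phase), advances the continuous
differentiation, runs the growth-factor reaction-diffusion update and
applies medium changes when due.

Measurements mirror the cell-culture observables: live cell count,
viability (live over live plus cumulative dead, in percent), DNA content
(proportional to live cells), ALP as the early-differentiation marker
(cells below the maturity threshold weighted by maturity / m_t), OC as the
late marker (cells above threshold weighted by (maturity - m_t) /
(1 - m_t)) and the medium concentrations of TGF-beta1 and BMP2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agents import (alkalinity, cycle_bias, migration_chance, update_internal_ph)
from .environment import EnvironmentState, PhModel
from .fuzzy import FuzzyController, default_controller
from .lattice import EMPTY, LatticeWorld
from .params import ParameterSet

__all__ = ["ExperimentProtocol", "Simulation", "run", "OBSERVABLES"]

OBSERVABLES = ("live_count", "viability", "dna", "alp", "oc", "tgfb1", "bmp2")


@dataclass(frozen=True)
class ExperimentProtocol:
    """One culture condition and its measurement schedule."""

    mg_mM: float
    seed_count: int = 200
    duration_days: float = 3.0
    schedule: tuple[tuple[float, tuple[str, ...]], ...] = ((3.0, ("live_count", "viability")),)
    world_shape: tuple[int, int, int] = (30, 30, 8)
    medium_change: bool = True
    normalize_gf_by_dna: bool = False

    def __post_init__(self) -> None:
        if self.mg_mM < 0:
            raise ValueError("Mg concentration must be non-negative")
        for day, observables in self.schedule:
            if day > self.duration_days:
                raise ValueError(f"measurement day {day} beyond protocol duration")
            unknown = set(observables) - set(OBSERVABLES)
            if unknown:
                raise ValueError(f"unknown observables {sorted(unknown)}")

    @property
    def duration_h(self) -> int:
        return int(round(self.duration_days * 24))


class Simulation:
    """State and stepping of a single replicate."""

    def __init__(self, protocol: ExperimentProtocol, params: ParameterSet | None = None,
                 controller: FuzzyController | None = None, seed: int | np.random.SeedSequence = 0,
                 ph_model: PhModel | None = None, check_invariants: bool = False,
                 log_events: bool = False) -> None:
        self.protocol = protocol
        self.params = params or ParameterSet()
        self.controller = controller or default_controller(self.params)
        self.check_invariants = check_invariants
        self.log_events = log_events
        self.events: list[tuple] = []
        seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        self.rng = np.random.default_rng(seq)
        self.t_h = 0.0

        nx, ny, nz = protocol.world_shape
        self.world = LatticeWorld(nx, ny, nz)
        self.env = EnvironmentState(
            mg_mM=protocol.mg_mM, shape=protocol.world_shape,
            ph_model=ph_model or PhModel(),
            duration_h=protocol.duration_h if protocol.medium_change else 0.0,
        )
        self._seed_cells()
        self.cum_dead = 0

    # -- initialisation ----------------------------------------------------

    def _seed_cells(self) -> None:
        p = self.params
        nx, ny, _ = self.protocol.world_shape
        n = self.protocol.seed_count
        if n > nx * ny:
            raise ValueError("seeding count exceeds the capacity of the surface layer")
        flat = self.rng.choice(nx * ny, size=n, replace=False)
        xs, ys = np.divmod(flat, ny)
        self.pos = np.column_stack([xs, ys, np.zeros(n, dtype=np.int64)]).astype(np.int64)
        self.maturity = np.zeros(n)
        self.dna_damage = (self.rng.random(n) < p.gamma_c).astype(np.int8)
        self.internal_ph = np.full(n, self.env.ph_model.ph0)
        # asynchronous culture: cycle clocks start uniformly inside a cycle
        self.clock = self.rng.uniform(0.0, p.t_cyc, n)
        self.delta_p = np.zeros(n, dtype=np.int8)
        self.delta_p_age = np.zeros(n)
        self.alive = np.ones(n, dtype=bool)
        for i in range(n):
            self.world.place(i, tuple(self.pos[i]))

    # -- stepping ----------------------------------------------------------

    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())

    def step(self) -> None:
        """Advance the simulation by one hour."""
        p = self.params
        dt = 1.0
        self.t_h += dt
        live = np.flatnonzero(self.alive)
        if live.size:
            self._step_cells(live, dt)
        # growth-factor dynamics react to the post-event configuration
        cell_mask = self.world.occupancy != EMPTY
        early_mask = np.zeros(self.world.shape, dtype=bool)
        live = np.flatnonzero(self.alive)
        if live.size:
            early = live[self.maturity[live] < p.m_t]
            early_mask[tuple(self.pos[early].T)] = True
        self.env.react_and_diffuse(cell_mask, early_mask, p.wc, dt)
        if self.protocol.medium_change and self.env.medium_change_due(self.t_h):
            self.env.medium_change()
        if self.check_invariants:
            self.world.check_consistency(self.pos, self.alive)

    def _step_cells(self, live: np.ndarray, dt: float) -> None:
        p = self.params
        rng = self.rng
        # intracellular state updates
        self.internal_ph[live] = update_internal_ph(self.internal_ph[live], self.env.ambient_ph, p.r_r, dt)
        if self.env.ambient_ph >= p.ph_t:
            self.dna_damage[live] = 1
        self.clock[live] += dt
        aging = live[self.delta_p[live] == 1]
        self.delta_p_age[aging] += dt
        expired = aging[self.delta_p_age[aging] >= p.delta_p_persistence]
        self.delta_p[expired] = 0
        self.delta_p_age[expired] = 0.0

        # fuzzy controller, one batch over the live population
        density = self.world.density_field()[tuple(self.pos[live].T)]
        out = self.controller.evaluate_batch({
            "maturity": self.maturity[live],
            "dna_damage": self.dna_damage[live].astype(float),
            "mg": np.full(live.size, self.env.mg_mM),
            "alkalinity": alkalinity(self.internal_ph[live], self.env.ambient_ph),
            "bmp2": self.env.fields["bmp2"].conc[tuple(self.pos[live].T)],
            "tgfb1": self.env.fields["tgfb1"].conc[tuple(self.pos[live].T)],
            "density": density,
        })

        p_die = np.clip((1.0 + p.alpha_pm * self.delta_p[live]) * p.alpha_m * out["mortality"] * p.gamma_m0, 0.0, 1.0)
        p_div = np.clip(cycle_bias(self.clock[live], p) * p.alpha_p * out["proliferation"] * p.gamma_p0, 0.0, 1.0)
        p_mig = migration_chance(out["migration"])
        draws = rng.random((3, live.size))

        # phase 1: mortality
        died = live[draws[0] < p_die]
        for i in died:
            self.world.remove(tuple(self.pos[i]))
            if self.log_events:
                self._log("death", i)
        self.alive[died] = False
        self.cum_dead += died.size
        survivors = np.isin(live, died, invert=True, assume_unique=True) if died.size else np.ones(live.size, dtype=bool)

        # phase 2: proliferation, in random visiting order
        world = self.world
        occ_flat = world._occ_flat
        shape = world.shape
        dividers = live[(draws[1] < p_div) & survivors]
        new_cells: list[tuple] = []
        if dividers.size:
            flats = np.ravel_multi_index(tuple(self.pos[dividers].T), shape)
            order = rng.permutation(dividers.size)
            for i, f in zip(dividers[order], flats[order]):
                vacant = world.vacant_neighbors_flat(int(f))
                if vacant.size == 0:
                    continue  # deferred until a neighbour frees up
                dst_flat = int(vacant[rng.integers(vacant.size)])
                new_id = self.alive.size + len(new_cells)
                occ_flat[dst_flat] = new_id
                self.clock[i] = 0.0
                mother_gets_flag = rng.random() < 0.5
                if mother_gets_flag:
                    self.delta_p[i], self.delta_p_age[i] = 1, 0.0
                else:
                    self.delta_p[i], self.delta_p_age[i] = 0, 0.0
                dst = np.unravel_index(dst_flat, shape)
                new_cells.append((dst, self.maturity[i], self.dna_damage[i],
                                  self.internal_ph[i], 0 if mother_gets_flag else 1))
                if self.log_events:
                    self._log("division", i)

        # phase 3: migration, in random visiting order
        movers = live[(draws[2] < p_mig) & survivors]
        if movers.size:
            flats = np.ravel_multi_index(tuple(self.pos[movers].T), shape)
            order = rng.permutation(movers.size)
            for i, f in zip(movers[order], flats[order]):
                vacant = world.vacant_neighbors_flat(int(f))
                if vacant.size == 0:
                    continue
                dst_flat = int(vacant[rng.integers(vacant.size)])
                occ_flat[dst_flat] = i
                occ_flat[int(f)] = EMPTY
                self.pos[i] = np.unravel_index(dst_flat, shape)
                if self.log_events:
                    self._log("migration", i)

        # phase 4: continuous differentiation (may co-occur with division)
        f_d = np.where(self.maturity[live] < p.m_t, out["early_differentiation"], out["late_differentiation"])
        gained = p.alpha_d * f_d * p.r_d0 * dt
        self.maturity[live] = np.minimum(self.maturity[live] + np.where(survivors, gained, 0.0), 1.0)

        if new_cells:
            self._append_cells(new_cells)

    def _append_cells(self, new_cells: list[tuple]) -> None:
        k = len(new_cells)
        self.pos = np.vstack([self.pos, np.asarray([c[0] for c in new_cells], dtype=np.int64)])
        self.maturity = np.append(self.maturity, [c[1] for c in new_cells])
        self.dna_damage = np.append(self.dna_damage, np.asarray([c[2] for c in new_cells], dtype=np.int8))
        self.internal_ph = np.append(self.internal_ph, [c[3] for c in new_cells])
        self.clock = np.append(self.clock, np.zeros(k))
        self.delta_p = np.append(self.delta_p, np.asarray([c[4] for c in new_cells], dtype=np.int8))
        self.delta_p_age = np.append(self.delta_p_age, np.zeros(k))
        self.alive = np.append(self.alive, np.ones(k, dtype=bool))

    # -- audit outputs -----------------------------------------------------

    def _log(self, event: str, cell_id: int) -> None:
        x, y, z = (int(v) for v in self.pos[cell_id])
        self.events.append((int(round(self.t_h)), int(cell_id), event, x, y, z))

    def event_log(self) -> pd.DataFrame:
        """Event audit trail (requires ``log_events=True``): one row per
        death/division/migration with step, cell id and patch."""
        return pd.DataFrame(self.events, columns=["step", "cell_id", "event", "x", "y", "z"])

    def snapshot(self) -> pd.DataFrame:
        """Current cell table for visualisation: id, patch, maturity, state."""
        rows = []
        for i in range(self.alive.size):
            x, y, z = (int(v) for v in self.pos[i])
            rows.append({
                "cell_id": i, "x": x, "y": y, "z": z,
                "maturity": float(self.maturity[i]),
                "dna_damage": int(self.dna_damage[i]),
                "alive": bool(self.alive[i]),
            })
        return pd.DataFrame(rows)

    # -- measurement -------------------------------------------------------

    def measure(self, observables: tuple[str, ...] = OBSERVABLES) -> dict[str, float]:
        """Summary statistics of the current state."""
        p = self.params
        live = np.flatnonzero(self.alive)
        n_live = live.size
        row: dict[str, float] = {}
        m = self.maturity[live]
        for obs in observables:
            if obs == "live_count":
                row[obs] = float(n_live)
            elif obs == "viability":
                total = n_live + self.cum_dead
                row[obs] = 100.0 * n_live / total if total else 0.0
            elif obs == "dna":
                row[obs] = p.kappa_dna * n_live
            elif obs == "alp":
                early = m[m < p.m_t]
                row[obs] = float(p.kappa_alp * np.sum(early / p.m_t))
            elif obs == "oc":
                late = m[m >= p.m_t]
                row[obs] = float(p.kappa_oc * np.sum((late - p.m_t) / (1.0 - p.m_t)))
            elif obs in ("tgfb1", "bmp2"):
                value = self.env.fields[obs].mean_concentration
                if self.protocol.normalize_gf_by_dna:
                    dna = p.kappa_dna * n_live
                    value = value / dna if dna else 0.0
                row[obs] = value
            else:
                raise ValueError(f"unknown observable {obs!r}")
        return row

    def run(self) -> pd.DataFrame:
        """Run the full protocol; one tidy row per scheduled measurement."""
        schedule = {int(round(day * 24)): tuple(obs) for day, obs in self.protocol.schedule}
        rows = []
        if 0 in schedule:
            rows.extend(self._measure_rows(0.0, schedule[0]))
        for _ in range(self.protocol.duration_h):
            self.step()
            hour = int(round(self.t_h))
            if hour in schedule:
                rows.extend(self._measure_rows(hour / 24.0, schedule[hour]))
        return pd.DataFrame(rows, columns=["condition", "day", "observable", "value"])

    def _measure_rows(self, day: float, observables: tuple[str, ...]) -> list[dict]:
        values = self.measure(observables)
        return [
            {"condition": self.protocol.mg_mM, "day": day, "observable": obs, "value": values[obs]}
            for obs in observables
        ]


def run(protocols, params: ParameterSet | None = None, seed: int = 0, replicates: int = 1,
        controller: FuzzyController | None = None, ph_model: PhModel | None = None,
        check_invariants: bool = False):
    """Run one or more protocols with replicate seeds.

    Returns ``(summary, raw)``: ``raw`` holds one row per (replicate,
    condition, day, observable); ``summary`` aggregates mean and sd across
    replicates (sd is 0 for a single replicate).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if isinstance(protocols, ExperimentProtocol):
        protocols = [protocols]
    tables = []
    for protocol in protocols:
        # identical replicate seeds across conditions: paired comparisons
        children = np.random.SeedSequence(seed).spawn(replicates)
        for rep, child in enumerate(children):
            sim = Simulation(protocol, params=params, controller=controller,
                             seed=child, ph_model=ph_model, check_invariants=check_invariants)
            table = sim.run()
            table.insert(0, "replicate", rep)
            tables.append(table)
    raw = pd.concat(tables, ignore_index=True)
    summary = (
        raw.groupby(["condition", "day", "observable"], as_index=False)["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0)
    )
    return summary, raw
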