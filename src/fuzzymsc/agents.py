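"""MSC agent state and the stochastic cellular event equations.

Each hourly step a cell's decision controller emits action intensities
fP, fM, fMi, fD in [0, 1] which enter the event equations:

    proliferation chance = Omega(clock) * alpha_p * fP * gamma_p0
    mortality chance     = (1 + alpha_pm * delta_p) * alpha_m * fM * gamma_m0
    migration chance     = fMi
    differentiation rate = alpha_d * fD * r_d0

with probabilities clamped to [0, 1]. Omega is a logistic bias in the time
since the last division that concentrates proliferation near the end of
the cell cycle; delta_p is the transient mitotic-damage flag carried by
one daughter after each division. fD is the early- or late-differentiation
channel depending on whether maturity has crossed the threshold m_t.

The chance functions are numpy-vectorised so the simulation engine can
evaluate whole populations per step; :class:`CellAgent` is the one-cell
view used for single-agent work and tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ParameterSet

__all__ = [
    "CellAgent",
    "cycle_bias",
    "proliferation_chance",
    "mortality_chance",
    "migration_chance",
    "differentiation_rate",
    "update_internal_ph",
    "alkalinity",
    "check_dna_damage",
    "execute_events",
]


def cycle_bias(clock_h, params: ParameterSet):
    """Logistic cell-cycle bias Omega(t) = 1 / (1 + exp(-k (t - T_cyc)))."""
    t = np.asarray(clock_h, dtype=float)
    return 1.0 / (1.0 + np.exp(-params.k_omega * (t - params.t_cyc)))


def proliferation_chance(clock_h, f_p, params: ParameterSet):
    """Per-step division probability, clamped to [0, 1]."""
    _check_nonneg(params)
    return np.clip(cycle_bias(clock_h, params) * params.alpha_p * np.asarray(f_p) * params.gamma_p0, 0.0, 1.0)


def mortality_chance(delta_p, f_m, params: ParameterSet):
    """Per-step death probability, amplified by the mitotic-damage flag."""
    _check_nonneg(params)
    return np.clip((1.0 + params.alpha_pm * np.asarray(delta_p)) * params.alpha_m * np.asarray(f_m) * params.gamma_m0, 0.0, 1.0)


def migration_chance(f_mi):
    """Per-step relocation probability; the controller output verbatim."""
    return np.clip(np.asarray(f_mi, dtype=float), 0.0, 1.0)


def differentiation_rate(maturity, f_d_early, f_d_late, params: ParameterSet):
    """Maturity gain per hour; channel selected by the maturity threshold."""
    m = np.asarray(maturity, dtype=float)
    f_d = np.where(m < params.m_t, np.asarray(f_d_early), np.asarray(f_d_late))
    return params.alpha_d * f_d * params.r_d0


def update_internal_ph(internal_ph, ambient_ph, r_r: float, dt: float):
    """Relax internal pH toward ambient at constant rate, never overshooting."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    internal = np.asarray(internal_ph, dtype=float)
    gap = ambient_ph - internal
    step = np.minimum(np.abs(gap), r_r * dt)
    return internal + np.sign(gap) * step


def alkalinity(internal_ph, ambient_ph):
    """Controller input: ambient minus internal pH, clamped at zero."""
    return np.maximum(np.asarray(ambient_ph, dtype=float) - np.asarray(internal_ph, dtype=float), 0.0)


def check_dna_damage(damaged, ambient_ph, params: ParameterSet, *, is_init: bool,
                     rng: np.random.Generator):
    """Absorbing DNA-damage update.

    At initialisation cells are damaged with the base chance ``gamma_c``
    (cell-passaging injury); thereafter one hour at or above the pH
    threshold ``ph_t`` damages deterministically. Damage never reverts.
    """
    d = np.asarray(damaged, dtype=np.int8).copy()
    if is_init:
        d |= (rng.random(d.shape) < params.gamma_c).astype(np.int8)
    if np.asarray(ambient_ph) >= params.ph_t:
        d[...] = 1
    return d


def _check_nonneg(params: ParameterSet) -> None:
    # ParameterSet validates at construction; guard ad-hoc replacements too.
    if min(params.gamma_p0, params.gamma_m0, params.alpha_p, params.alpha_m,
           params.alpha_pm, params.alpha_d) < 0:
        raise ValueError("chance parameters must be non-negative")


@dataclass
class CellAgent:
    """One mesenchymal stem cell.

    ``maturity`` grows monotonically from 0 (naive MSC) toward 1 (mature
    osteoblast); ``cycle_clock`` is hours since the last division;
    ``delta_p`` flags the transient post-mitotic vulnerability.
    """

    position: tuple[int, int, int]
    maturity: float = 0.0
    dna_damage: int = 0
    internal_ph: float = 7.4
    cycle_clock: float = 0.0
    delta_p: int = 0
    delta_p_age: float = 0.0
    alive: bool = True

    def update_internal_ph(self, ambient_ph: float, r_r: float, dt: float = 1.0) -> None:
        self.internal_ph = float(update_internal_ph(self.internal_ph, ambient_ph, r_r, dt))

    def alkalinity(self, ambient_ph: float) -> float:
        return float(alkalinity(self.internal_ph, ambient_ph))

    def differentiate(self, f_d_early: float, f_d_late: float, params: ParameterSet,
                      dt: float = 1.0) -> float:
        """Advance maturity by the continuous differentiation rate, capped at 1."""
        rate = float(differentiation_rate(self.maturity, f_d_early, f_d_late, params))
        self.maturity = min(self.maturity + rate * dt, 1.0)
        return self.maturity


def execute_events(cell: CellAgent, world, output, params: ParameterSet,
                   rng: np.random.Generator, dt: float = 1.0,
                   daughter_id: int | None = None) -> dict:
    """Run one cell's stochastic events for one step.

    Order: mortality, then proliferation, then migration, then the always-
    continuous differentiation. Division places the daughter on a random
    vacant neighbouring patch (deferred when fully surrounded) and assigns
    the mitotic-damage flag delta_p to exactly one of the pair; migration
    moves the cell one patch to a random vacant neighbour; death frees the
    patch. The daughter is registered in the world immediately (under
    ``daughter_id``, or the next free id) and returned in the event record
    under ``"daughter"``. The mother cell must already be registered.
    """
    if not cell.alive:
        raise ValueError("dead cells take no actions")
    record: dict = {"died": False, "divided": False, "migrated": False, "daughter": None}

    cell.cycle_clock += dt
    if cell.delta_p:
        cell.delta_p_age += dt
        if cell.delta_p_age >= params.delta_p_persistence:
            cell.delta_p = 0
            cell.delta_p_age = 0.0

    p_die = float(mortality_chance(cell.delta_p, output.mortality, params))
    p_div = float(proliferation_chance(cell.cycle_clock, output.proliferation, params))
    p_mig = float(migration_chance(output.migration))

    if rng.random() < p_die:
        cell.alive = False
        world.remove(cell.position)
        record["died"] = True
        return record

    if rng.random() < p_div:
        vacant = world.vacant_neighbors(cell.position)
        if vacant:  # otherwise division is deferred until space frees up
            dst = vacant[rng.integers(len(vacant))]
            daughter = CellAgent(
                position=tuple(int(v) for v in dst),
                maturity=cell.maturity,
                dna_damage=cell.dna_damage,
                internal_ph=cell.internal_ph,
            )
            if daughter_id is None:
                daughter_id = int(world.occupancy.max()) + 1
            world.place(daughter_id, daughter.position)
            cell.cycle_clock = 0.0
            if rng.random() < 0.5:
                cell.delta_p, cell.delta_p_age = 1, 0.0
                daughter.delta_p = 0
            else:
                daughter.delta_p, daughter.delta_p_age = 1, 0.0
                cell.delta_p, cell.delta_p_age = 0, 0.0
            record["divided"] = True
            record["daughter"] = daughter

    if rng.random() < p_mig:
        vacant = world.vacant_neighbors(cell.position)
        if vacant:
            dst = vacant[rng.integers(len(vacant))]
            world.move(cell.position, dst)
            cell.position = tuple(int(v) for v in dst)
            record["migrated"] = True

    cell.differentiate(output.early_differentiation, output.late_differentiation, params, dt)
    return record
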