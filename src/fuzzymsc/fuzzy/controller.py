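"""Mamdani-type fuzzy controller for the cellular decision process.

The controller maps seven crisp cellular inputs (maturity, DNA damage,
Mg2+, alkalinity, BMP2, TGF-beta1, local cell density) to five action
intensities in [0, 1]: proliferation, mortality, migration and the early
and late differentiation channels. It works in the classic three steps —
fuzzification through the registered membership functions, rule firing
with min/max norms, and weighted-fuzzy-mean defuzzification where every
fired rule contributes its firing strength times the representative value
of its consequent level.

The whole pipeline is vectorised: :meth:`FuzzyController.evaluate_batch`
evaluates all cells of a simulation step in one numpy pass, and
:meth:`FuzzyController.evaluate` is the single-cell convenience wrapper.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .membership import LinguisticInput
from .rules import ACTIONS, RuleBase

__all__ = ["ControllerOutput", "FuzzyController", "INPUT_NAMES"]

INPUT_NAMES = ("maturity", "dna_damage", "mg", "alkalinity", "bmp2", "tgfb1", "density")


@dataclass(frozen=True)
class ControllerOutput:
    """Crisp action intensities for one cell, all in [0, 1]."""

    proliferation: float
    mortality: float
    migration: float
    early_differentiation: float
    late_differentiation: float

    @property
    def f_p(self) -> float:
        return self.proliferation

    @property
    def f_m(self) -> float:
        return self.mortality

    @property
    def f_mi(self) -> float:
        return self.migration

    def f_d(self, maturity: float, maturity_threshold: float) -> float:
        """Differentiation channel selected by the maturity threshold."""
        if maturity < maturity_threshold:
            return self.early_differentiation
        return self.late_differentiation


@dataclass
class FuzzyController:
    """Fuzzification + rule inference + defuzzification.

    Parameters
    ----------
    inputs
        Mapping of input name -> :class:`LinguisticInput`; must cover
        :data:`INPUT_NAMES`.
    rule_base
        The rule table and per-action output scales.
    default_output
        Crisp value returned for an action when no rule fires (the
        conservative null action).
    """

    inputs: dict[str, LinguisticInput]
    rule_base: RuleBase
    default_output: float = 0.0
    _compiled: list | None = field(default=None, repr=False, compare=False)
    _no_fire_logged: set = field(default_factory=set, repr=False, compare=False)

    def __post_init__(self) -> None:
        missing = [n for n in INPUT_NAMES if n not in self.inputs]
        if missing:
            raise ValueError(f"controller is missing inputs: {missing}")
        self.rule_base.validate(self.inputs)
        self._compile()

    # -- compilation -------------------------------------------------------

    def _compile(self) -> None:
        """Pre-resolve the rule base into flat index/weight arrays.

        Batch evaluation then reduces to: gather level degrees into one
        matrix (with a zero dummy column so ragged allowed-level sets can
        be padded), take clause maxima, reduce clauses to rule strengths
        (``minimum.reduceat`` for AND rules, k-th largest for the any-k
        combinators), and fold strengths into per-action weighted sums by
        two matrix products.
        """
        # global column layout: dummy zero column, then each input's levels
        offsets = {}
        col = 1
        for name in INPUT_NAMES:
            offsets[name] = col
            col += len(self.inputs[name].levels)
        self._n_cols = col

        def clause_cols(clause) -> list[int]:
            names = self.inputs[clause.input].level_names
            allowed = clause.allowed(names)
            if not allowed:
                raise ValueError("clause allows no level at all")
            return [offsets[clause.input] + names.index(l) for l in allowed]

        simple = [r for r in self.rule_base.rules if r.combinator == "all" and r.clauses]
        constant = [r for r in self.rule_base.rules if not r.clauses]
        complex_ = [r for r in self.rule_base.rules if r.combinator != "all"]

        clause_idx: list[list[int]] = []
        self._simple_starts = []
        for rule in simple:
            self._simple_starts.append(len(clause_idx))
            clause_idx.extend(clause_cols(c) for c in rule.clauses)
        self._complex_segments = []
        for rule in complex_:
            start = len(clause_idx)
            clause_idx.extend(clause_cols(c) for c in rule.clauses)
            self._complex_segments.append((start, len(clause_idx), rule.combinator))
        kmax = max((len(c) for c in clause_idx), default=1)
        self._clause_idx = np.asarray(
            [c + [0] * (kmax - len(c)) for c in clause_idx], dtype=np.intp
        )
        # reduceat runs each segment to the next start, so bound the last
        # simple rule's segment at the first complex clause
        if complex_ and simple:
            self._simple_starts.append(self._complex_segments[0][0])
        self._simple_starts = np.asarray(self._simple_starts, dtype=np.intp)

        actions = list(ACTIONS)
        ordered = simple + complex_
        self._rep_weights = np.zeros((len(ordered), len(actions)))
        self._indicator = np.zeros((len(ordered), len(actions)))
        for r, rule in enumerate(ordered):
            a = actions.index(rule.action)
            self._rep_weights[r, a] = self.rule_base.scales[rule.action].rep(rule.level)
            self._indicator[r, a] = 1.0
        self._const_num = np.zeros(len(actions))
        self._const_den = np.zeros(len(actions))
        for rule in constant:  # empty antecedent: fires at strength 1 always
            a = actions.index(rule.action)
            self._const_num[a] += self.rule_base.scales[rule.action].rep(rule.level)
            self._const_den[a] += 1.0
        self._n_simple = len(simple)

    # -- the three Mamdani steps ------------------------------------------

    def fuzzify(self, input_name: str, value: float) -> dict[str, float]:
        """Step 1 for one input: crisp value -> level membership degrees."""
        if input_name not in self.inputs:
            raise KeyError(f"unknown input {input_name!r}")
        return self.inputs[input_name].fuzzify(value)

    def fire_rule(self, rule, fuzzified: dict[str, dict[str, float]]) -> float:
        """Step 2 for one rule: activation strength from fuzzified inputs."""
        degrees = []
        for clause in rule.clauses:
            allowed = clause.allowed(self.inputs[clause.input].level_names)
            degrees.append(max(fuzzified[clause.input][l] for l in allowed))
        return float(_combine(np.asarray(degrees, dtype=float), rule.combinator))

    def defuzzify(self, action: str, level_strengths: dict[str, float]) -> float:
        """Step 3 for one action: weighted fuzzy mean of activated levels."""
        scale = self.rule_base.scales[action]
        num = sum(s * scale.rep(l) for l, s in level_strengths.items())
        den = sum(level_strengths.values())
        if den == 0.0:
            if action not in self._no_fire_logged:
                self._no_fire_logged.add(action)
            return self.default_output
        return num / den

    # -- full evaluation ---------------------------------------------------

    def evaluate(self, **values: float) -> ControllerOutput:
        """Evaluate the controller for one cell.

        Accepts the seven inputs as keyword arguments, e.g.
        ``evaluate(maturity=0.1, dna_damage=0, mg=3.0, alkalinity=0.0,
        bmp2=0.01, tgfb1=0.1, density=0.2)``.
        """
        missing = [n for n in INPUT_NAMES if n not in values]
        if missing:
            raise ValueError(f"missing inputs: {missing}")
        batch = {n: np.asarray([values[n]], dtype=float) for n in INPUT_NAMES}
        out = self.evaluate_batch(batch)
        return ControllerOutput(**{a: float(out[a][0]) for a in ACTIONS})

    def evaluate_batch(self, values: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        """Evaluate the controller for ``n`` cells at once.

        ``values`` maps each input name to an (n,) array; returns a dict of
        (n,) arrays keyed by action.
        """
        n = np.asarray(values[INPUT_NAMES[0]]).size
        degrees = np.zeros((n, self._n_cols))
        col = 1
        for name in INPUT_NAMES:
            block = self.inputs[name].fuzzify_batch(np.asarray(values[name], dtype=float))
            degrees[:, col:col + block.shape[1]] = block
            col += block.shape[1]

        n_rules = self._rep_weights.shape[0]
        strengths = np.empty((n, n_rules))
        if self._clause_idx.size:
            clause_deg = degrees[:, self._clause_idx].max(axis=2)  # (n, n_clauses)
            if self._n_simple:
                strengths[:, :self._n_simple] = np.minimum.reduceat(
                    clause_deg, self._simple_starts, axis=1
                )[:, :self._n_simple]
            for k, (start, stop, combinator) in enumerate(self._complex_segments):
                strengths[:, self._n_simple + k] = _combine(
                    clause_deg[:, start:stop], combinator, axis=1
                )

        num = strengths @ self._rep_weights + self._const_num
        den = strengths @ self._indicator + self._const_den
        out = {}
        for j, a in enumerate(ACTIONS):
            d = den[:, j]
            fired = d > 0.0
            out[a] = np.where(fired, num[:, j] / np.where(fired, d, 1.0), self.default_output)
        return out

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "inputs": [self.inputs[n].to_dict() for n in INPUT_NAMES],
            "rule_base": self.rule_base.to_dict(),
            "default_output": float(self.default_output),
        }

    @staticmethod
    def from_dict(d: dict) -> "FuzzyController":
        inputs = {i["name"]: LinguisticInput.from_dict(i) for i in d["inputs"]}
        return FuzzyController(
            inputs=inputs,
            rule_base=RuleBase.from_dict(d["rule_base"]),
            default_output=float(d.get("default_output", 0.0)),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @staticmethod
    def from_yaml(text: str) -> "FuzzyController":
        return FuzzyController.from_dict(yaml.safe_load(text))


def _combine(degrees: np.ndarray, combinator: str, axis: int = 0) -> np.ndarray:
    """Aggregate clause degrees under min/max norms.

    ``all`` is the min t-norm, ``any`` the max s-norm, and ``any2`` the
    second-largest degree, which equals the explicit expansion of "any two
    or more" as an OR over all conjunctions of size >= 2.
    """
    if combinator == "all":
        return degrees.min(axis=axis)
    if combinator == "any":
        return degrees.max(axis=axis)
    if combinator == "any2":
        s = np.sort(degrees, axis=axis)
        return np.take(s, s.shape[axis] - 2, axis=axis)
    raise ValueError(f"unknown combinator {combinator!r}")
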