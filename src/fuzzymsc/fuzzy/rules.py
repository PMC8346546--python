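"""Fuzzy IF-THEN rules linking cellular inputs to action intensities.

A rule's antecedent is a list of clauses, each naming an input and the
level(s) that satisfy it (possibly negated). Clauses are combined by the
rule's combinator:

``all``
    every clause must hold (AND, t-norm),
``any``
    at least one clause must hold (OR, s-norm),
``any2``
    at least two clauses must hold.

An omitted input acts as a wildcard; a rule with an empty antecedent fires
unconditionally at strength 1 (used for baseline action levels). Under the
default min/max norms the ``any2`` combinator equals the second-largest
clause degree, which is exactly the max-over-subsets-of-min expansion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

__all__ = ["Clause", "FuzzyRule", "OutputScale", "RuleBase", "ACTIONS"]

ACTIONS = (
    "proliferation",
    "mortality",
    "migration",
    "early_differentiation",
    "late_differentiation",
)

COMBINATORS = ("all", "any", "any2")


@dataclass(frozen=True)
class Clause:
    """One antecedent condition: ``input`` is at one of ``levels``.

    ``negate=True`` inverts the level set ("Not stimulatory" matches every
    level except stimulatory).
    """

    input: str
    levels: tuple[str, ...]
    negate: bool = False

    def allowed(self, all_levels: list[str]) -> tuple[str, ...]:
        if self.negate:
            return tuple(l for l in all_levels if l not in self.levels)
        return self.levels

    def to_dict(self) -> dict:
        d: dict = {"input": self.input, "levels": list(self.levels)}
        if self.negate:
            d["negate"] = True
        return d

    @staticmethod
    def from_dict(d: dict) -> "Clause":
        levels = d.get("levels", d.get("level"))
        if isinstance(levels, str):
            levels = [levels]
        return Clause(d["input"], tuple(levels), bool(d.get("negate", False)))


@dataclass(frozen=True)
class FuzzyRule:
    """IF <clauses, combined by combinator> THEN <action is level>."""

    clauses: tuple[Clause, ...]
    action: str
    level: str
    combinator: str = "all"

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise ValueError(f"unknown action {self.action!r}")
        if self.combinator not in COMBINATORS:
            raise ValueError(f"unknown combinator {self.combinator!r}")
        if self.combinator == "any2" and len(self.clauses) < 2:
            raise ValueError("any2 combinator needs at least two clauses")

    def to_dict(self) -> dict:
        d: dict = {
            "if": [c.to_dict() for c in self.clauses],
            "then": {"action": self.action, "level": self.level},
        }
        if self.combinator != "all":
            d["combinator"] = self.combinator
        return d

    @staticmethod
    def from_dict(d: dict) -> "FuzzyRule":
        return FuzzyRule(
            clauses=tuple(Clause.from_dict(c) for c in d.get("if", [])),
            action=d["then"]["action"],
            level=d["then"]["level"],
            combinator=d.get("combinator", "all"),
        )


@dataclass
class OutputScale:
    """Ordered output levels of one action with representative crisp values."""

    action: str
    levels: list[str]
    reps: list[float]

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.reps):
            raise ValueError("levels and reps must align")
        if any(r < 0 or r > 1 for r in self.reps):
            raise ValueError("representative values must lie in [0, 1]")
        if any(b <= a for a, b in zip(self.reps, self.reps[1:])):
            raise ValueError("representative values must strictly increase")

    def rep(self, level: str) -> float:
        return self.reps[self.levels.index(level)]

    def to_dict(self) -> dict:
        return {"action": self.action, "levels": list(self.levels), "reps": [float(r) for r in self.reps]}

    @staticmethod
    def from_dict(d: dict) -> "OutputScale":
        return OutputScale(d["action"], list(d["levels"]), [float(r) for r in d["reps"]])


@dataclass
class RuleBase:
    """The full rule table plus output scales, serialisable to YAML."""

    rules: list[FuzzyRule] = field(default_factory=list)
    scales: dict[str, OutputScale] = field(default_factory=dict)

    def validate(self, inputs: dict[str, "object"]) -> None:
        """Check every referenced input/level/action exists.

        ``inputs`` maps input name -> LinguisticInput.
        """
        for rule in self.rules:
            for clause in rule.clauses:
                if clause.input not in inputs:
                    raise ValueError(f"rule references unknown input {clause.input!r}")
                names = inputs[clause.input].level_names
                for lvl in clause.levels:
                    if lvl not in names:
                        raise ValueError(
                            f"rule references unknown level {lvl!r} of input {clause.input!r}"
                        )
            if rule.action not in self.scales:
                raise ValueError(f"no output scale for action {rule.action!r}")
            if rule.level not in self.scales[rule.action].levels:
                raise ValueError(
                    f"rule consequent level {rule.level!r} missing from scale of {rule.action!r}"
                )

    def to_dict(self) -> dict:
        return {
            "rules": [r.to_dict() for r in self.rules],
            "scales": [s.to_dict() for s in self.scales.values()],
        }

    @staticmethod
    def from_dict(d: dict) -> "RuleBase":
        scales = [OutputScale.from_dict(s) for s in d.get("scales", [])]
        return RuleBase(
            rules=[FuzzyRule.from_dict(r) for r in d.get("rules", [])],
            scales={s.action: s for s in scales},
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @staticmethod
    def from_yaml(text: str) -> "RuleBase":
        return RuleBase.from_dict(yaml.safe_load(text))
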