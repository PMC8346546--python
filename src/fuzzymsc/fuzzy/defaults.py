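"""Default linguistic inputs and rule base.

The membership breakpoints encode the concentration bands reported in the
experimental literature for each cue: Mg2+ below the 0.8 mM culture-medium
background is negligible, the 2-10 mM band stimulates proliferation and
early differentiation (peak at ``cmlt``), concentrations above ~1.8 mM
inhibit late differentiation and mineralisation, and the 20-40 mM band is
cytotoxic (peak at ``cmht``). BMP2 acts from 0.008 ng/mL, stimulates at
10-20 ng/mL, is neutral at 50-200 and inhibitory at 500-2000 ng/mL.
TGF-beta1 acts from 0.05 ng/mL with a stimulatory plateau over the
physiological 14.2-36.3 ng/mL range. Alkalinity is the gap between ambient
and cell-internal pH; the severe level peaks at ``a_t``. Density
breakpoints ``cclt1..ccht2`` separate solitude, normal crowding and
contact inhibition.

The default rule table transcribes those qualitative effects as IF-THEN
rules; it is data, not code — load a different YAML rule base to change
cellular logic.
"""

from __future__ import annotations

from ..params import ParameterSet
from .controller import FuzzyController
from .membership import LinguisticInput, MembershipFunction as MF
from .rules import Clause, FuzzyRule, OutputScale, RuleBase

__all__ = ["default_inputs", "default_rule_base", "default_controller", "OUTPUT_LEVELS"]

#: Evenly spaced representative values for the five action outputs.
OUTPUT_LEVELS = (("zero", 0.0), ("low", 0.25), ("medium", 0.5), ("high", 0.75), ("full", 1.0))


def default_inputs(params: ParameterSet | None = None) -> dict[str, LinguisticInput]:
    p = params or ParameterSet()
    mg = LinguisticInput("mg", [
        MF.shoulder_left("negligible", 0.8, 2.0),
        MF("inhibitory", ((1.8, 0.0), (p.cmlt, 1.0))),
        MF.triangle("stimulatory", 2.0, p.cmlt, 10.0),
        MF.triangle("high", p.cmlt, p.cmmt, p.cmht),
        MF.shoulder_right("destructive", p.cmmt, p.cmht),
    ])
    alkalinity = LinguisticInput("alkalinity", [
        MF.shoulder_left("negligible", 0.10, 0.25),
        MF.trapezoid("mild", 0.10, 0.25, p.a_t - 0.15, p.a_t),
        MF.shoulder_right("severe", p.a_t - 0.15, p.a_t),
    ])
    bmp2 = LinguisticInput("bmp2", [
        MF.shoulder_left("negligible", 0.004, 0.008),
        MF.trapezoid("stimulatory", 0.008, 10.0, 20.0, 50.0),
        MF.trapezoid("neutral", 20.0, 50.0, 200.0, 500.0),
        MF.shoulder_right("inhibitory", 200.0, 500.0),
    ])
    tgfb1 = LinguisticInput("tgfb1", [
        MF.shoulder_left("negligible", 0.02, 0.05),
        MF.trapezoid("stimulatory", 0.05, 14.2, 36.3, 60.0),
        MF.shoulder_right("high", 36.3, 60.0),
    ])
    density = LinguisticInput("density", [
        MF.shoulder_left("low", p.cclt1, p.cclt2),
        MF.trapezoid("medium", p.cclt1, p.cclt2, p.ccht1, p.ccht2),
        MF.shoulder_right("high", p.ccht1, p.ccht2),
    ])
    maturity = LinguisticInput("maturity", [
        MF.shoulder_left("early", max(p.m_t - 0.1, 0.0), min(p.m_t + 0.1, 1.0)),
        MF.shoulder_right("late", max(p.m_t - 0.1, 0.0), min(p.m_t + 0.1, 1.0)),
    ])
    dna_damage = LinguisticInput("dna_damage", [
        MF.shoulder_left("low", 0.25, 0.75),
        MF.shoulder_right("high", 0.25, 0.75),
    ], crisp=True)
    return {i.name: i for i in (maturity, dna_damage, mg, alkalinity, bmp2, tgfb1, density)}


def _rule(action: str, level: str, *clauses, combinator: str = "all") -> FuzzyRule:
    cs = []
    for input_name, levels in clauses:
        negate = isinstance(levels, str) and levels.startswith("not:")
        if negate:
            levels = levels[4:]
        if isinstance(levels, str):
            levels = (levels,)
        cs.append(Clause(input_name, tuple(levels), negate))
    return FuzzyRule(tuple(cs), action, level, combinator)


def default_rule_base() -> RuleBase:
    scales = {
        action: OutputScale(action, [l for l, _ in OUTPUT_LEVELS], [r for _, r in OUTPUT_LEVELS])
        for action in ("proliferation", "mortality", "migration",
                       "early_differentiation", "late_differentiation")
    }
    r = _rule
    rules = [
        # -- proliferation ------------------------------------------------
        r("proliferation", "medium", ("maturity", "early")),       # MSC baseline
        r("proliferation", "low", ("maturity", "late")),           # declining capacity
        r("proliferation", "high", ("mg", "stimulatory")),
        r("proliferation", "low", ("mg", "high")),
        r("proliferation", "zero", ("mg", "destructive")),
        r("proliferation", "low", ("alkalinity", "mild")),
        r("proliferation", "zero", ("alkalinity", "severe")),
        r("proliferation", "high", ("bmp2", "stimulatory")),
        r("proliferation", "low", ("bmp2", "inhibitory")),
        r("proliferation", "high", ("tgfb1", "stimulatory")),
        r("proliferation", "low", ("density", "high")),            # contact inhibition
        r("proliferation", "low", ("density", "low")),             # solitude
        r("proliferation", "low", ("dna_damage", "high")),
        # -- mortality ----------------------------------------------------
        r("mortality", "low"),                                     # baseline attrition
        r("mortality", "full", ("mg", "destructive")),
        r("mortality", "high", ("alkalinity", "severe")),
        r("mortality", "high", ("bmp2", "inhibitory")),
        r("mortality", "zero", ("tgfb1", "stimulatory")),          # blocks apoptosis
        r("mortality", "medium", ("density", "high")),
        r("mortality", "medium", ("density", "low")),
        r("mortality", "high", ("dna_damage", "high")),
        r("mortality", "full",                                     # compound insult
          ("mg", "destructive"), ("alkalinity", "severe"), ("dna_damage", "high"),
          combinator="any2"),
        # -- migration (driven by contact inhibition) ---------------------
        r("migration", "high", ("density", "high")),
        r("migration", "low", ("density", "medium")),
        r("migration", "zero", ("density", "low")),
        # -- early differentiation ---------------------------------------
        r("early_differentiation", "low"),                         # baseline commitment
        r("early_differentiation", "high", ("mg", "stimulatory")),
        r("early_differentiation", "high", ("bmp2", "stimulatory")),
        r("early_differentiation", "high", ("tgfb1", "stimulatory")),
        r("early_differentiation", "high", ("density", "high")),   # onset by crowding
        r("early_differentiation", "zero", ("alkalinity", "severe")),
        # -- late differentiation ----------------------------------------
        r("late_differentiation", "medium"),                       # baseline progression
        r("late_differentiation", "zero", ("mg", "inhibitory")),   # mineralisation block
        r("late_differentiation", "zero", ("tgfb1", "stimulatory")),
        r("late_differentiation", "high", ("bmp2", "stimulatory")),
        r("late_differentiation", "zero", ("alkalinity", "severe")),
    ]
    return RuleBase(rules=rules, scales=scales)


def default_controller(params: ParameterSet | None = None) -> FuzzyController:
    """The stock controller: default memberships plus the default rules."""
    return FuzzyController(inputs=default_inputs(params), rule_base=default_rule_base())
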