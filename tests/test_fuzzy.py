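"""Membership functions, rule firing and the Mamdani controller."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fuzzymsc.fuzzy import (Clause, FuzzyController, FuzzyRule, LinguisticInput,
                            MembershipFunction, OutputScale, RuleBase, default_controller)

from _oracle import evaluate as oracle_evaluate


class TestMembership:
    def test_mg_below_background_is_purely_negligible(self, controller):
        degrees = controller.fuzzify("mg", 0.4)
        assert degrees["negligible"] == 1.0
        for level in ("inhibitory", "stimulatory", "high", "destructive"):
            assert degrees[level] == 0.0

    def test_mg_at_cmlt_peaks_stimulatory(self, controller, params):
        degrees = controller.fuzzify("mg", params.cmlt)
        assert degrees["stimulatory"] == 1.0
        assert degrees["high"] == 0.0
        assert degrees["destructive"] == 0.0

    def test_mg_midpoint_blends_adjacent_levels(self, controller, params):
        # midway down the stimulatory flank (cmlt..10) and up the high flank
        x = (params.cmlt + 10.0) / 2.0  # 7.25 mM
        degrees = controller.fuzzify("mg", x)
        assert degrees["stimulatory"] == pytest.approx((10.0 - x) / (10.0 - params.cmlt))
        assert degrees["high"] == pytest.approx((x - params.cmlt) / (params.cmmt - params.cmlt))

    def test_crisp_dna_damage_activates_exactly_one_level(self, controller):
        assert controller.fuzzify("dna_damage", 0.0) == {"low": 1.0, "high": 0.0}
        assert controller.fuzzify("dna_damage", 1.0) == {"low": 0.0, "high": 1.0}
        with pytest.raises(ValueError):
            controller.fuzzify("dna_damage", 0.5)

    def test_shoulders_saturate_beyond_outer_breakpoint(self, controller):
        assert controller.fuzzify("mg", 500.0)["destructive"] == 1.0

    def test_errors(self, controller):
        with pytest.raises(KeyError):
            controller.fuzzify("oxygen", 1.0)
        with pytest.raises(ValueError):
            controller.fuzzify("mg", -1.0)
        with pytest.raises(ValueError):
            MembershipFunction("bad", ((1.0, 0.0), (0.5, 1.0)))
        with pytest.raises(ValueError):
            MembershipFunction("bad", ((0.0, 0.0), (1.0, 1.5)))

    @settings(derandomize=True, max_examples=200)
    @given(x=st.floats(min_value=0.0, max_value=1e4, allow_nan=False))
    def test_membership_degrees_always_bounded(self, x):
        controller = default_controller()
        for name in ("mg", "alkalinity", "bmp2", "tgfb1"):
            for degree in controller.fuzzify(name, x).values():
                assert 0.0 <= degree <= 1.0


class TestRuleFiring:
    def _fuzzified(self, controller, **values):
        return {name: controller.fuzzify(name, v) for name, v in values.items()}

    def test_unit_degrees_give_unit_strength(self, controller):
        rule = FuzzyRule((Clause("mg", ("negligible",)),), "proliferation", "medium")
        fz = self._fuzzified(controller, mg=0.4)
        assert controller.fire_rule(rule, fz) == 1.0

    def test_zero_degree_annihilates_single_clause(self, controller):
        rule = FuzzyRule((Clause("mg", ("destructive",)),), "mortality", "full")
        fz = self._fuzzified(controller, mg=0.4)
        assert controller.fire_rule(rule, fz) == 0.0

    def test_min_tnorm_on_mixed_degrees(self, controller, params):
        # mg 3.0 -> stimulatory (3-2)/(cmlt-2)=0.4; density 0.2 -> low (0.25-0.2)/0.15=1/3
        rule = FuzzyRule(
            (Clause("mg", ("stimulatory",)), Clause("density", ("low",))),
            "proliferation", "high",
        )
        fz = self._fuzzified(controller, mg=3.0, density=0.2)
        expected = min(fz["mg"]["stimulatory"], fz["density"]["low"])
        assert controller.fire_rule(rule, fz) == pytest.approx(expected)
        assert expected == pytest.approx(1.0 / 3.0)

    def test_any_combinators_match_subset_enumeration(self, controller):
        from _oracle import rule_strength

        fz = self._fuzzified(controller, mg=7.25, alkalinity=0.18, density=0.2)
        for combinator in ("any", "any2"):
            rule = FuzzyRule(
                (Clause("mg", ("high",)), Clause("alkalinity", ("mild",)),
                 Clause("density", ("low",))),
                "mortality", "high", combinator=combinator,
            )
            assert controller.fire_rule(rule, fz) == pytest.approx(
                rule_strength(rule, controller.inputs, fz), abs=1e-15
            )

    def test_negated_clause_matches_complement(self, controller):
        rule = FuzzyRule((Clause("mg", ("stimulatory",), negate=True),), "mortality", "low")
        fz = self._fuzzified(controller, mg=4.5)  # stimulatory=1, inhibitory=1
        assert controller.fire_rule(rule, fz) == 1.0  # inhibitory alone saturates


class TestDefuzzification:
    def test_single_activated_level_returns_its_rep(self, controller):
        assert controller.defuzzify("proliferation", {"high": 0.42}) == pytest.approx(0.75)

    def test_weighted_mean_of_two_levels(self, controller):
        value = controller.defuzzify("proliferation", {"low": 0.3, "high": 0.6})
        assert value == pytest.approx((0.3 * 0.25 + 0.6 * 0.75) / 0.9)

    def test_no_activation_returns_default(self, controller):
        assert controller.defuzzify("proliferation", {}) == 0.0


class TestController:
    NEUTRAL = dict(maturity=0.1, dna_damage=0.0, mg=0.4, alkalinity=0.0,
                   bmp2=0.001, tgfb1=0.01, density=0.4)

    def test_wildcard_only_rule_base_returns_rep(self, controller):
        scales = {"mortality": OutputScale("mortality", ["low", "high"], [0.25, 0.75])}
        rb = RuleBase(rules=[FuzzyRule((), "mortality", "high")], scales=scales)
        mini = FuzzyController(inputs=controller.inputs, rule_base=rb)
        out = mini.evaluate(**self.NEUTRAL)
        assert out.mortality == 0.75
        assert out.proliferation == 0.0  # no rule for that action -> default

    def test_outputs_bounded_on_wide_random_inputs(self, controller, rng):
        from conftest import random_input_batch

        batch = random_input_batch(rng, 2000)
        out = controller.evaluate_batch(batch)
        for action, values in out.items():
            assert np.all(values >= 0.0) and np.all(values <= 1.0), action

    def test_matches_bruteforce_oracle_on_random_inputs(self, controller, rng):
        from conftest import random_input_batch

        batch = random_input_batch(rng, 500)
        out = controller.evaluate_batch(batch)
        for i in range(500):
            values = {k: float(v[i]) for k, v in batch.items()}
            expected = oracle_evaluate(controller, values)
            for action in expected:
                assert out[action][i] == pytest.approx(expected[action], abs=1e-12)

    def test_dna_damage_raises_mortality_output(self, controller):
        base = dict(self.NEUTRAL)
        healthy = controller.evaluate(**base)
        base["dna_damage"] = 1.0
        damaged = controller.evaluate(**base)
        assert damaged.mortality > healthy.mortality
        assert damaged.proliferation < healthy.proliferation

    def test_proliferation_monotone_in_stimulatory_mg(self, controller, params):
        # sweep the rising stimulatory flank with everything else neutral
        values = dict(self.NEUTRAL)
        outputs = []
        for mg in np.linspace(2.0, params.cmlt, 15):
            values["mg"] = mg
            outputs.append(controller.evaluate(**values).proliferation)
        assert np.all(np.diff(outputs) >= -1e-15)

    def test_differentiation_channel_selection(self, controller, params):
        out = controller.evaluate(**self.NEUTRAL)
        assert out.f_d(0.1, params.m_t) == out.early_differentiation
        assert out.f_d(0.9, params.m_t) == out.late_differentiation

    def test_missing_input_is_an_error(self, controller):
        with pytest.raises(ValueError, match="missing"):
            controller.evaluate(maturity=0.0, dna_damage=0.0, mg=1.0)

    def test_unknown_rule_reference_rejected(self, controller):
        rb = RuleBase(
            rules=[FuzzyRule((Clause("mg", ("imaginary",)),), "mortality", "low")],
            scales=default_controller().rule_base.scales,
        )
        with pytest.raises(ValueError, match="unknown level"):
            FuzzyController(inputs=controller.inputs, rule_base=rb)


class TestSerialization:
    def test_yaml_round_trip_is_bit_identical(self, controller, rng):
        from conftest import random_input_batch

        clone = FuzzyController.from_yaml(controller.to_yaml())
        batch = random_input_batch(rng, 300)
        out_a = controller.evaluate_batch(batch)
        out_b = clone.evaluate_batch(batch)
        for action in out_a:
            np.testing.assert_array_equal(out_a[action], out_b[action])

    def test_level_and_input_structure_survive(self, controller):
        clone = FuzzyController.from_yaml(controller.to_yaml())
        assert [i.to_dict() for i in clone.inputs.values()] == \
               [i.to_dict() for i in controller.inputs.values()]
        assert clone.rule_base.to_dict() == controller.rule_base.to_dict()

    def test_output_scale_invariants(self):
        with pytest.raises(ValueError):
            OutputScale("mortality", ["low", "high"], [0.8, 0.2])
        with pytest.raises(ValueError):
            OutputScale("mortality", ["low", "high"], [0.2, 1.2])


def test_mg_input_has_five_levels_and_other_counts_match(controller):
    """The linguistic structure: 5 Mg levels, 3 alkalinity, 4 BMP2, 3 density, 2 maturity."""
    counts = {name: len(inp.levels) for name, inp in controller.inputs.items()}
    assert counts["mg"] == 5
    assert counts["alkalinity"] == 3
    assert counts["bmp2"] == 4
    assert counts["density"] == 3
    assert counts["maturity"] == 2
    assert controller.inputs["dna_damage"].crisp
    # TGF-beta1 stimulation starts at 0.05 ng/mL
    tgf = controller.inputs["tgfb1"]
    stim = next(mf for mf in tgf.levels if mf.name == "stimulatory")
    assert stim.points[0][0] == 0.05
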