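"""Calibration engine: fit metric, screening, ABC and the iterative loop.

The engine is simulator-agnostic, so these tests drive it with cheap
closed-form surrogates and check it against brute-force counterparts.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fuzzymsc.calibration import (CalibrationConfig, CalibrationState, ObservedDataset,
                                  abc_reject, ffd_design, ffd_screen, iterate,
                                  narrowing_test, r_squared, select_top)
from fuzzymsc.params import Prior


def _table(values: dict[float, float], observable="live_count", day=3.0):
    return pd.DataFrame(
        [{"condition": c, "day": day, "observable": observable, "mean": v}
         for c, v in values.items()]
    )


def _sim_table(values: dict[float, float], observable="live_count", day=3.0):
    t = _table(values, observable, day)
    return t.rename(columns={"mean": "value"})


class TestRSquared:
    def test_perfect_match_is_one(self):
        obs = _table({0.8: 100.0, 3.0: 150.0})
        assert r_squared(_sim_table({0.8: 100.0, 3.0: 150.0}), obs) == 1.0

    def test_zero_prediction_is_zero(self):
        obs = _table({0.8: 100.0, 3.0: 150.0})
        assert r_squared(_sim_table({0.8: 0.0, 3.0: 0.0}), obs) == 0.0

    def test_uniform_ten_percent_error_gives_09(self):
        obs = _table({0.8: 100.0, 3.0: 150.0})
        sim = _sim_table({0.8: 110.0, 3.0: 165.0})
        assert r_squared(sim, obs) == pytest.approx(0.9)

    def test_averaged_over_observables(self):
        obs = pd.concat([_table({0.8: 100.0}), _table({0.8: 10.0}, observable="dna")],
                        ignore_index=True)
        sim = pd.concat([_sim_table({0.8: 100.0}), _sim_table({0.8: 0.0}, observable="dna")],
                        ignore_index=True)
        assert r_squared(sim, obs) == pytest.approx(0.5)

    def test_missing_key_is_an_error(self):
        obs = _table({0.8: 100.0, 3.0: 150.0})
        with pytest.raises(ValueError, match="lacks"):
            r_squared(_sim_table({0.8: 100.0}), obs)


class TestFFD:
    def test_design_is_orthogonal_and_balanced(self):
        for p in (3, 5, 11, 20):
            d = ffd_design(p)
            assert d.shape[1] == p
            assert np.all(np.abs(d) == 1.0)
            np.testing.assert_array_equal(d.sum(axis=0), np.zeros(p))  # balance
            gram = d.T @ d
            np.testing.assert_array_equal(gram, d.shape[0] * np.eye(p))  # orthogonality

    def test_foldover_removes_two_way_aliasing(self):
        # resolution IV: main-effect columns orthogonal to every pairwise product
        d = ffd_design(7)
        for i, j in itertools.combinations(range(7), 2):
            interaction = d[:, i] * d[:, j]
            assert np.abs(d.T @ interaction).max() == 0.0

    @staticmethod
    def _surrogate(coeffs, noise_sd=0.0):
        obs = _table({0.8: 0.0})

        def simulate(values, seed):
            rng = np.random.default_rng(seed)
            y = sum(c * values[k] for k, c in coeffs.items())
            y += noise_sd * rng.standard_normal()
            return _sim_table({0.8: y})

        return ObservedDataset(obs.assign(mean=1.0)), simulate

    def test_dominant_parameter_ranked_first(self):
        data, simulate = self._surrogate({"a": 3.0, "b": 0.1}, noise_sd=0.05)
        priors = {"a": Prior("a", 0.0, 1.0), "b": Prior("b", 0.0, 1.0)}
        effects = ffd_screen(priors, simulate, data, seed=0)
        assert effects.idxmax() == "a"
        assert effects["a"] == 1.0  # scaled to the maximum

    def test_null_parameter_has_negligible_effect(self):
        data, simulate = self._surrogate({"a": 3.0, "b": 0.0, "c": 1.0}, noise_sd=0.01)
        priors = {k: Prior(k, 0.0, 1.0) for k in "abc"}
        effects = ffd_screen(priors, simulate, data, seed=1)
        assert effects["b"] < 0.05 * effects["a"]

    def test_matches_full_factorial_oracle_on_linear_surrogate(self):
        # keep y below 1 so the fit metric 1 - |y - 1| is affine in y and
        # the fractional main effects must equal the full-factorial ones
        coeffs = {"a": 0.2, "b": -0.1, "c": 0.05}
        data, simulate = self._surrogate(coeffs)
        priors = {k: Prior(k, 0.0, 1.0) for k in "abc"}
        effects = ffd_screen(priors, simulate, data, seed=2)
        # brute-force full factorial: enumerate all corners, average halves
        corners = list(itertools.product([0.0, 1.0], repeat=3))
        ys = {c: sum(coeffs[k] * v for k, v in zip("abc", c)) for c in corners}
        oracle = {}
        for axis, name in enumerate("abc"):
            hi = np.mean([y for c, y in ys.items() if c[axis] == 1.0])
            lo = np.mean([y for c, y in ys.items() if c[axis] == 0.0])
            oracle[name] = abs(hi - lo)
        oracle_scaled = {k: v / max(oracle.values()) for k, v in oracle.items()}
        # the fit metric is affine in y here, so scaled main effects agree
        for name in "abc":
            assert effects[name] == pytest.approx(oracle_scaled[name], abs=1e-9)

    def test_viability_penalty_keeps_effects_finite(self):
        obs = _table({0.8: 1.0})
        data = ObservedDataset(obs, min_viability=50.0)

        def simulate(values, seed):
            sim = _sim_table({0.8: values["a"]})
            viab = _sim_table({0.8: 100.0 if values["a"] > 0.5 else 10.0},
                              observable="viability")
            return pd.concat([sim, viab], ignore_index=True)

        priors = {"a": Prior("a", 0.0, 1.0), "b": Prior("b", 0.0, 1.0)}
        effects = ffd_screen(priors, simulate, data, seed=5)
        assert np.isfinite(effects).all()
        assert effects.idxmax() == "a"

    def test_needs_two_parameters(self):
        data, simulate = self._surrogate({"a": 1.0})
        with pytest.raises(ValueError):
            ffd_screen({"a": Prior("a", 0.0, 1.0)}, simulate, data, seed=0)


class TestSelectTop:
    def test_whole_pool_returned_when_k_equals_size(self):
        effects = pd.Series({"a": 0.9, "b": 0.5, "c": 0.1, "d": 0.3, "e": 0.2})
        assert set(select_top(effects, 5)) == set("abcde")

    def test_exact_top_k_by_magnitude(self):
        effects = pd.Series({"a": 0.9, "b": 0.5, "c": 0.1, "d": 0.3, "e": 0.2})
        assert select_top(effects, 2) == ["a", "b"]

    def test_ties_break_lexicographically(self):
        effects = pd.Series({"zz": 0.5, "aa": 0.5, "mm": 0.5})
        assert select_top(effects, 2) == ["aa", "mm"]

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            select_top(pd.Series({"a": 1.0}), 2)


class TestAbcReject:
    @staticmethod
    def _linear_setup(target=0.6):
        obs = _table({0.8: target})
        data = ObservedDataset(obs)

        def simulate(values, seed):
            return _sim_table({0.8: values["a"]})

        return data, simulate

    def test_keep_all_returns_prior_sample(self):
        data, simulate = self._linear_setup()
        priors = {"a": Prior("a", 0.0, 1.0)}
        post = abc_reject(priors, simulate, data, n_runs=200, n_keep=200, seed=0)
        assert len(post) == 200
        # a uniform prior sample: KS against U(0,1) must not reject
        assert stats.kstest(post["a"], "uniform").pvalue > 0.01

    def test_flat_distance_leaves_prior_untouched(self):
        obs = _table({0.8: 1.0})
        data = ObservedDataset(obs)

        def simulate(values, seed):
            return _sim_table({0.8: 1.0})  # data-free: identical fit always

        priors = {"a": Prior("a", 0.0, 1.0)}
        post = abc_reject(priors, simulate, data, n_runs=400, n_keep=100, seed=1)
        assert stats.kstest(post["a"], "uniform").pvalue > 0.01

    def test_posterior_concentrates_on_truth(self):
        data, simulate = self._linear_setup(target=0.6)
        priors = {"a": Prior("a", 0.0, 1.0)}
        post = abc_reject(priors, simulate, data, n_runs=500, n_keep=20, seed=2)
        assert post["a"].median() == pytest.approx(0.6, abs=0.05)
        assert post["r2"].iloc[0] >= post["r2"].iloc[-1]  # sorted best-first

    def test_viability_constraint_flags_degenerate_posterior(self):
        obs = _table({0.8: 1.0})
        data = ObservedDataset(obs, min_viability=50.0)

        def simulate(values, seed):
            sim = _sim_table({0.8: values["a"]})
            viab = _sim_table({0.8: 10.0}, observable="viability")
            return pd.concat([sim, viab], ignore_index=True)

        priors = {"a": Prior("a", 0.0, 1.0)}
        post = abc_reject(priors, simulate, data, n_runs=50, n_keep=10, seed=3)
        assert post.attrs["degenerate"]

    def test_n_keep_exceeding_runs_rejected(self):
        data, simulate = self._linear_setup()
        with pytest.raises(ValueError):
            abc_reject({"a": Prior("a", 0, 1)}, simulate, data, n_runs=10, n_keep=11, seed=0)


class TestNarrowing:
    PRIOR = Prior("a", 0.0, 1.0)

    def test_prior_sample_rejected(self, rng):
        sample = rng.uniform(0, 1, 500)
        assert not narrowing_test(sample, self.PRIOR)

    def test_degenerate_posterior_accepted(self):
        assert narrowing_test(np.full(100, 0.37), self.PRIOR)

    def test_boundary_is_strict(self):
        # IQR exactly rho * 0.5 * range -> reject
        boundary = np.array([0.0, 0.0, 0.25, 0.25])
        assert np.percentile(boundary, 75) - np.percentile(boundary, 25) == 0.25
        assert not narrowing_test(boundary, self.PRIOR, rho=0.5)
        assert narrowing_test(boundary * 0.99, self.PRIOR, rho=0.5)

    def test_empty_posterior_rejected(self):
        with pytest.raises(ValueError):
            narrowing_test(np.array([]), self.PRIOR)


class TestIterate:
    @staticmethod
    def _recovery_setup(truth):
        obs = pd.DataFrame([
            {"condition": c, "day": 3.0, "observable": "live_count",
             "mean": truth["a"] * c + truth["b"]}
            for c in (1.0, 2.0, 4.0)
        ])

        def simulate(values, seed):
            return pd.DataFrame([
                {"condition": c, "day": 3.0, "observable": "live_count",
                 "value": values["a"] * c + values["b"]}
                for c in (1.0, 2.0, 4.0)
            ])

        return ObservedDataset(obs), simulate

    def test_zero_free_parameters_terminates_immediately(self):
        data, simulate = self._recovery_setup({"a": 1.0, "b": 0.0})
        state = iterate(CalibrationState(free={}), simulate, data, seed=0)
        assert state.iteration == 0 and state.records == []

    def test_identifiable_surrogate_recovers_and_terminates(self):
        truth = {"a": 0.7, "b": 0.4}
        data, simulate = self._recovery_setup(truth)
        free = {"a": Prior("a", 0.0, 1.0), "b": Prior("b", 0.0, 1.0)}
        config = CalibrationConfig(n_runs=400, n_keep=20, max_iterations=5)
        state = iterate(CalibrationState(free=dict(free)), simulate, data, config, seed=4)
        assert set(state.fixed) == {"a", "b"}  # everything inferred
        for name, value in truth.items():
            assert state.fixed[name] == pytest.approx(value, abs=0.1)
        # once the pool is empty the loop stops on its own
        assert state.iteration <= config.max_iterations
        assert state.records[-1]["accepted"]

    def test_r2_trace_recorded_per_iteration(self):
        data, simulate = self._recovery_setup({"a": 0.7, "b": 0.4})
        free = {"a": Prior("a", 0.0, 1.0), "b": Prior("b", 0.0, 1.0)}
        config = CalibrationConfig(n_runs=200, n_keep=20, max_iterations=3)
        state = iterate(CalibrationState(free=dict(free)), simulate, data, config, seed=5)
        for rec in state.records:
            assert np.isfinite(rec["r2_mean"])
            assert rec["r2_sd"] >= 0.0
            assert len(rec["selected"]) <= config.k_top

    def test_free_and_fixed_stay_disjoint(self):
        data, simulate = self._recovery_setup({"a": 0.7, "b": 0.4})
        free = {"a": Prior("a", 0.0, 1.0), "b": Prior("b", 0.0, 1.0)}
        state = iterate(CalibrationState(free=dict(free)), simulate, data,
                        CalibrationConfig(n_runs=100, n_keep=10, max_iterations=2), seed=6)
        assert not (set(state.free) & set(state.fixed))
        assert set(state.free) | set(state.fixed) == {"a", "b"}

    def test_state_rejects_overlapping_partition(self):
        with pytest.raises(ValueError):
            CalibrationState(free={"a": Prior("a", 0, 1)}, fixed={"a": 0.5})
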