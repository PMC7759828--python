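"""Weighted survival loss, Breslow baseline, curves, RMST, effect weights."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emusurv import (DeepSurvivalModel, SimConfig, SurvivalCurve,
                     breslow_baseline, expected_survival, fit_weighted_cox,
                     risk_sets, simulate_cohort, weighted_loss)
from emusurv.survival import _loss_and_grad


class TestWeightedLoss:
    def test_single_event_subject_zero_loss(self):
        assert weighted_loss([3.7], [5.0], [1], [1.0]) == pytest.approx(0.0)

    def test_all_events_zero_output_log_n_factorial_over_n(self):
        n = 7
        Y = np.arange(1.0, n + 1)
        val = weighted_loss(np.zeros(n), Y, np.ones(n), np.ones(n))
        assert val == pytest.approx(math.log(math.factorial(n)) / n)

    def test_three_subject_hand_sum(self):
        # times 1,2,3; d = 1,0,1; g = 0.5,-0.2,0.1; w = 2,1,1
        g = np.array([0.5, -0.2, 0.1])
        hand = -(2 * (0.5 - np.log(np.exp(0.5) + np.exp(-0.2) + np.exp(0.1)))
                 + 1 * (0.1 - np.log(np.exp(0.1)))) / 2.0
        val = weighted_loss(g, [1.0, 2.0, 3.0], [1, 0, 1], [2.0, 1.0, 1.0])
        assert val == pytest.approx(hand, rel=1e-12)

    def test_zero_events_errors(self):
        with pytest.raises(ValueError, match="zero events"):
            weighted_loss([0.1, 0.2], [1.0, 2.0], [0, 0], [1.0, 1.0])

    @settings(max_examples=25, derandomize=True)
    @given(st.floats(-5, 5))
    def test_shift_invariance(self, c):
        rng = np.random.default_rng(1)
        n = 20
        g = rng.normal(size=n)
        Y = rng.exponential(1, n)
        d = rng.binomial(1, 0.6, n)
        d[0] = 1
        w = rng.uniform(0.5, 3, n)
        assert weighted_loss(g + c, Y, d, w) == pytest.approx(
            weighted_loss(g, Y, d, w), rel=1e-9, abs=1e-9)

    def test_weight_scaling_scales_loss_same_optimum(self, fifty_row_survival):
        Y, d, x, z, w = fifty_row_survival
        g = np.random.default_rng(2).normal(size=len(Y))
        assert weighted_loss(g, Y, d, 2 * w) == pytest.approx(
            2 * weighted_loss(g, Y, d, w))

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        n = 25
        g = rng.normal(size=n)
        Y = rng.exponential(1, n).round(1)  # induce ties
        d = rng.binomial(1, 0.6, n).astype(float)
        d[0] = 1
        w = rng.uniform(0.5, 3, n)
        _, grad = _loss_and_grad(g, Y, d, w)
        eps = 1e-6
        for k in range(n):
            gp, gm = g.copy(), g.copy()
            gp[k] += eps
            gm[k] -= eps
            num = (weighted_loss(gp, Y, d, w) - weighted_loss(gm, Y, d, w)) / (2 * eps)
            assert grad[k] == pytest.approx(num, abs=1e-6)

    def test_strict_risk_set_drops_last_event(self):
        # strict inequality empties the last event's risk set
        val = weighted_loss([0.0, 0.0], [1.0, 2.0], [1, 1], [1.0, 1.0],
                            strict_risk=True)
        # only the first event contributes: 0 - log(exp(0)) = 0
        assert val == pytest.approx(0.0)

    def test_risk_sets_nested_and_include_self(self):
        Y = np.array([3.0, 1.0, 2.0, 2.0])
        d = np.array([1, 1, 1, 0])
        rs = risk_sets(Y, d)
        assert 0 in rs[0] and 1 in rs[1] and 2 in rs[2]
        assert set(rs[0]) <= set(rs[2]) <= set(rs[1])


class TestBreslow:
    def test_single_event_unit_increment(self):
        bh = breslow_baseline([0.0], [2.0], [1], [1.0])
        assert bh.increments[0] == pytest.approx(1.0)

    def test_weight_doubling_invariance(self, fifty_row_survival):
        Y, d, x, z, w = fifty_row_survival
        g = np.random.default_rng(3).normal(size=len(Y))
        a = breslow_baseline(g, Y, d, w)
        b = breslow_baseline(g, Y, d, 2 * w)
        np.testing.assert_allclose(a.increments, b.increments)

    def test_three_subject_hand_computation(self):
        # times 1,2,3; events 1,0,1; g = 0.5,-0.2,0.1; w = 2,1,1
        g = np.array([0.5, -0.2, 0.1])
        bh = breslow_baseline(g, [1.0, 2.0, 3.0], [1, 0, 1], [2.0, 1.0, 1.0])
        den1 = 2 * np.exp(0.5) + 1 * np.exp(-0.2) + 1 * np.exp(0.1)
        np.testing.assert_allclose(bh.increments,
                                   [2.0 / den1, 1.0 / np.exp(0.1)])
        assert np.all(np.diff(bh.cumhaz) >= 0)


class TestCurvesAndRMST:
    def test_zero_risk_curve_equals_baseline_survival(self, fifty_row_survival):
        Y, d, x, z, w = fifty_row_survival
        m = DeepSurvivalModel(Y, d, x, z, weights=w, hidden=())
        res = m.fit(learning_rate=0.05, epochs=5, seed=0)
        for wmat in res.network.weights:
            wmat[:] = 0.0
        for b in res.network.biases:
            b[:] = 0.0
        from emusurv.survival import breslow_baseline as bb
        res.baseline = bb(np.zeros(len(Y)), Y, d, w)
        c0 = res.marginal_survival(0)
        c1 = res.marginal_survival(1)
        np.testing.assert_allclose(c0.survival, c1.survival)
        np.testing.assert_allclose(
            c0.survival[1:], np.exp(-res.baseline.cumhaz))

    def test_curves_are_valid_survival_functions(self, fifty_row_survival):
        Y, d, x, z, w = fifty_row_survival
        res = DeepSurvivalModel(Y, d, x, z, weights=w, hidden=(8,)).fit(
            learning_rate=0.02, epochs=100, seed=0)
        for arm in (0, 1):
            c = res.marginal_survival(arm)
            assert c.survival[0] == 1.0 and c.times[0] == 0.0
            assert np.all(np.diff(c.survival) <= 1e-12)
            assert c.survival.min() >= 0.0 and c.survival.max() <= 1.0

    def test_invalid_arm(self, fifty_row_survival):
        Y, d, x, z, w = fifty_row_survival
        res = DeepSurvivalModel(Y, d, x, z, weights=w, hidden=()).fit(
            learning_rate=0.05, epochs=5, seed=0)
        with pytest.raises(ValueError):
            res.marginal_survival(2)

    def test_rmst_constant_one(self):
        c = SurvivalCurve([0.0, 10.0], [1.0, 1.0])
        assert expected_survival(c, 10.0) == pytest.approx(10.0)

    def test_rmst_exponential_closed_form(self):
        lam = 50.0
        t = np.linspace(0, 2000, 40001)
        c = SurvivalCurve(t, np.exp(-t / lam))
        assert expected_survival(c, 2000.0) == pytest.approx(lam, rel=2e-3)

    def test_rmst_step_curve_geometry(self):
        tau = 100.0
        c = SurvivalCurve([0.0, tau / 2, tau], [1.0, 0.5, 0.5])
        assert expected_survival(c, tau) == pytest.approx(0.75 * tau)

    def test_rmst_invalid_horizon(self):
        c = SurvivalCurve([0.0, 10.0], [1.0, 0.9])
        with pytest.raises(ValueError):
            expected_survival(c, -1.0)
        with pytest.raises(ValueError):
            expected_survival(c, 11.0)


class TestFitAndWeights:
    def test_linear_network_matches_weighted_cox(self, fifty_row_survival):
        Y, d, x, z, w = fifty_row_survival
        cox = fit_weighted_cox(Y, d, np.column_stack([x, z]), w)
        res = DeepSurvivalModel(Y, d, x, z, weights=w, hidden=()).fit(
            learning_rate=0.05, epochs=4000, seed=0)
        acc = res.accumulated_weights().to_numpy()
        assert np.max(np.abs((acc - cox.params) / cox.params)) < 1e-3

    def test_treatment_only_recovers_log_hazard_ratio(self):
        """Marginal two-group fit on randomized proportional-hazards data."""
        import dataclasses
        base = SimConfig(n_beneficiaries=5000, seed=31,
                         ps_coefficients={"intercept": 0.0})
        spec = dataclasses.replace(base.long_term,
                                   treatment_log_hr=float(np.log(0.7)),
                                   covariate_log_hr={})
        cohort, _ = simulate_cohort(base.replace(long_term=spec))
        Z = cohort["treatment"].to_numpy()
        Y, d = cohort["y_long"].to_numpy(), cohort["d_long"].to_numpy()
        res = DeepSurvivalModel(Y, d, None, Z, hidden=()).fit(
            learning_rate=0.05, epochs=2000, seed=0)
        beta = res.accumulated_weights()["treatment"]
        se = fit_weighted_cox(Y, d, Z[:, None]).bse[0]
        assert abs(beta - np.log(0.7)) < 3 * se

    def test_weight_scaling_leaves_optimum_unchanged(self, fifty_row_survival):
        Y, d, x, z, w = fifty_row_survival
        a = DeepSurvivalModel(Y, d, x, z, weights=w, hidden=()).fit(
            learning_rate=0.05, epochs=3000, seed=0)
        b = DeepSurvivalModel(Y, d, x, z, weights=2 * w, hidden=()).fit(
            learning_rate=0.05, epochs=3000, seed=0)
        np.testing.assert_allclose(a.accumulated_weights(),
                                   b.accumulated_weights(), atol=1e-4)

    def test_accumulated_weights_identity_single_layer(self, fifty_row_survival):
        Y, d, x, z, w = fifty_row_survival
        res = DeepSurvivalModel(Y, d, x, z, weights=w, hidden=()).fit(
            learning_rate=0.05, epochs=5, seed=0)
        np.testing.assert_allclose(res.accumulated_weights().to_numpy(),
                                   res.network.weights[0][:, 0])

    def test_accumulated_weights_hand_product(self, fifty_row_survival):
        Y, d, x, z, w = fifty_row_survival
        res = DeepSurvivalModel(Y, d, x, z, weights=w, hidden=(2,)).fit(
            learning_rate=0.05, epochs=5, seed=0)
        W1 = np.array([[1.0, 2.0], [0.5, -1.0], [0.0, 1.0], [3.0, 0.0]])
        W2 = np.array([[2.0], [-1.0]])
        res.network.weights = [W1, W2]
        np.testing.assert_allclose(res.accumulated_weights().to_numpy(),
                                   (W1 @ W2)[:, 0])

    def test_zeroed_treatment_column_gives_zero_weight_and_equal_curves(
            self, fifty_row_survival):
        Y, d, x, z, w = fifty_row_survival
        res = DeepSurvivalModel(Y, d, x, z, weights=w, hidden=(4,)).fit(
            learning_rate=0.02, epochs=50, seed=0)
        res.network.weights[0][res.model.treatment_index, :] = 0.0
        assert res.accumulated_weights()["treatment"] == pytest.approx(0.0)
        np.testing.assert_allclose(res.marginal_survival(0).survival,
                                   res.marginal_survival(1).survival)

    def test_single_arm_errors(self, fifty_row_survival):
        Y, d, x, z, w = fifty_row_survival
        with pytest.raises(ValueError, match="both treatment arms"):
            DeepSurvivalModel(Y, d, x, np.zeros_like(z), weights=w)

    def test_nan_divergence_names_configuration(self, fifty_row_survival):
        Y, d, x, z, w = fifty_row_survival
        m = DeepSurvivalModel(Y, d, 1e6 * x, z, weights=w, hidden=(8,))
        with pytest.raises((FloatingPointError, ValueError)):
            m.fit(learning_rate=1e4, epochs=200, seed=0)
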