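"""Core network dynamics: activation, layer updates, equilibria, decisions."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lcachoice import (
    ChoiceSet,
    NetworkParams,
    estimate_choice_probabilities,
    layer_step,
    piecewise_linear,
    simulate_decision,
    sublayer_equilibrium,
    utility,
)
from lcachoice.network import attribute_inputs

from conftest import single_attribute_set


finite_floats = st.floats(min_value=-50, max_value=50, allow_nan=False)


class TestPiecewiseLinear:
    @pytest.mark.parametrize(
        "y, expected",
        [(1.5, 1.0), (0.3, 0.3), (-0.2, 0.0), (0.0, 0.0), (1.0, 1.0)],
    )
    def test_examples(self, y, expected):
        assert piecewise_linear(y) == expected

    def test_vectorized(self):
        out = piecewise_linear([-1.0, 0.4, 2.0])
        np.testing.assert_array_equal(out, [0.0, 0.4, 1.0])

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            piecewise_linear(np.nan)
        with pytest.raises(ValueError):
            piecewise_linear([0.2, np.inf])

    @given(finite_floats, finite_floats)
    def test_monotone_and_idempotent(self, a, b):
        lo, hi = min(a, b), max(a, b)
        f_lo, f_hi = piecewise_linear(lo), piecewise_linear(hi)
        assert f_lo <= f_hi
        assert piecewise_linear(f_lo) == f_lo  # already in [0, 1]


class TestLayerStep:
    def test_zero_state_passes_inputs(self):
        out = layer_step([0, 0, 0], [0.75, 0.5, 0.25], s=1.0, l=1.0)
        np.testing.assert_allclose(out, [0.75, 0.5, 0.25])

    def test_hand_evaluated_update(self):
        # node 1: f(0.5*0.75 - 0.7*(0.5+0.25) + 0.75) = 0.6, etc.
        out = layer_step([0.75, 0.5, 0.25], [0.75, 0.5, 0.25], s=0.5, l=0.7)
        np.testing.assert_allclose(out, [0.6, 0.05, 0.0], atol=1e-12)

    def test_pure_decay_without_feedback(self):
        out = layer_step([1, 0, 0], [0, 0, 0], s=0.0, l=0.0)
        np.testing.assert_array_equal(out, [0.0, 0.0, 0.0])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            layer_step([0.1, 0.2], [0.3], s=0.5, l=0.5)


def _clamped_linear_oracle(inputs, s, l, zero_nodes):
    """Independent equilibrium oracle: solve the linear fixed point with a
    declared set of nodes clamped at zero (valid when no node saturates at 1).
    """
    inputs = np.asarray(inputs, dtype=float)
    n = inputs.size
    active = [i for i in range(n) if i not in zero_nodes]
    k = len(active)
    A = np.full((k, k), l, dtype=float)
    np.fill_diagonal(A, 1.0 - s)
    sol = np.linalg.solve(A, inputs[active])
    out = np.zeros(n)
    out[active] = sol
    return out


class TestSublayerEquilibrium:
    def test_identity_at_zero_feedback(self, canonical_inputs):
        prof = sublayer_equilibrium(single_attribute_set(canonical_inputs), 0, 0.0, 0.0)
        assert prof.converged
        np.testing.assert_allclose(prof.alpha, canonical_inputs, atol=1e-9)

    def test_winner_take_all(self, canonical_inputs):
        prof = sublayer_equilibrium(single_attribute_set(canonical_inputs), 0, 0.5, 0.7)
        assert prof.converged
        np.testing.assert_allclose(prof.alpha, [1.0, 0.0, 0.0], atol=1e-9)

    def test_worst_suppression_matches_linear_solve(self, canonical_inputs):
        prof = sublayer_equilibrium(single_attribute_set(canonical_inputs), 0, 0.0, 0.3)
        assert prof.converged
        expected = _clamped_linear_oracle(canonical_inputs, 0.0, 0.3, {2})
        np.testing.assert_allclose(expected, [0.65934065934066, 0.30219780219780, 0.0])
        np.testing.assert_allclose(prof.alpha, expected, atol=1e-8)

    def test_interior_equilibrium_matches_linear_solve(self, canonical_inputs):
        prof = sublayer_equilibrium(single_attribute_set(canonical_inputs), 0, 0.1, 0.1)
        expected = _clamped_linear_oracle(canonical_inputs, 0.1, 0.1, set())
        np.testing.assert_allclose(expected, [0.76704545454545, 0.45454545454545,
                                              0.14204545454545])
        np.testing.assert_allclose(prof.alpha, expected, atol=1e-8)

    def test_nonconvergence_reported_not_raised(self):
        # s=0, l=1 flip-flops between extremes: a period-2 cycle
        prof = sublayer_equilibrium(single_attribute_set([0.75, 0.5, 0.25]), 0, 0.0, 1.0)
        assert not prof.converged
        assert prof.residual > 1e-3

    def test_order_preservation(self, rng):
        for _ in range(30):
            inputs = np.sort(rng.uniform(0.05, 0.95, size=4))[::-1]
            s, l = rng.uniform(0, 1, size=2)
            prof = sublayer_equilibrium(single_attribute_set(inputs), 0, s, l)
            if not prof.converged:
                continue
            diffs = np.diff(prof.alpha)  # inputs descending -> alpha descending
            assert np.all(diffs <= 1e-9)

    def test_monotone_in_self_feedback(self, rng):
        """Without inhibition every node's equilibrium rises with s; with
        inhibition the input-maximal node still does (weaker nodes can be
        suppressed by the stronger inhibition a higher top node emits, so
        elementwise monotonicity only holds at l = 0)."""
        for _ in range(20):
            inputs = rng.uniform(0.05, 0.95, size=3)
            s_lo, s_hi = np.sort(rng.uniform(0, 1, size=2))
            p_lo = sublayer_equilibrium(single_attribute_set(inputs), 0, s_lo, 0.0)
            p_hi = sublayer_equilibrium(single_attribute_set(inputs), 0, s_hi, 0.0)
            if p_lo.converged and p_hi.converged:
                assert np.all(p_hi.alpha >= p_lo.alpha - 1e-8)
            l = rng.uniform(0, 1)
            q_lo = sublayer_equilibrium(single_attribute_set(inputs), 0, s_lo, l)
            q_hi = sublayer_equilibrium(single_attribute_set(inputs), 0, s_hi, l)
            if q_lo.converged and q_hi.converged:
                top = int(np.argmax(inputs))
                assert q_hi.alpha[top] >= q_lo.alpha[top] - 1e-8

    def test_saturation_thresholds_closed_form(self):
        x1, x2 = 0.75, 0.5
        inputs = [x1, x2, 0.25]
        # s above 1-x1 with l large enough: winner saturates at exactly 1
        prof = sublayer_equilibrium(single_attribute_set(inputs), 0, (1 - x1) + 0.05, x2 + 0.05)
        np.testing.assert_allclose(prof.alpha, [1.0, 0.0, 0.0], atol=1e-8)
        # s below 1-x1: winner stays at x1/(1-s) < 1 while the rest are suppressed
        s = (1 - x1) - 0.05
        prof = sublayer_equilibrium(single_attribute_set(inputs), 0, s, 0.6)
        assert prof.alpha[0] < 1.0
        np.testing.assert_allclose(prof.alpha, [x1 / (1 - s), 0.0, 0.0], atol=1e-8)
        # l below x2 with the winner at 1: runner-up keeps positive activation
        prof = sublayer_equilibrium(single_attribute_set(inputs), 0, 0.3, x2 - 0.05)
        assert prof.alpha[0] >= 1.0 - 1e-9
        assert prof.alpha[1] > 1e-6

    def test_unavailable_nodes_stay_off(self):
        cs = ChoiceSet(values=[[0.8], [0.3]], weights=[1.0],
                       available=[True, False, True])
        prof = sublayer_equilibrium(cs, 0, 0.2, 0.2)
        assert prof.alpha[1] == 0.0


class TestUtility:
    def test_worked_example(self, two_by_two_set):
        np.testing.assert_allclose(utility(two_by_two_set), [0.027, 0.0255])

    def test_single_attribute_unit_weight(self):
        cs = ChoiceSet(values=[[0.3], [0.7]], weights=[1.0])
        np.testing.assert_allclose(utility(cs), [0.3, 0.7])


class TestChoiceSetValidation:
    def test_rejects_boundary_values(self):
        with pytest.raises(ValueError, match="row 0, column 1"):
            ChoiceSet(values=[[0.5, 1.0]], weights=[1.0, 1.0])

    def test_rejects_weight_mismatch(self):
        with pytest.raises(ValueError):
            ChoiceSet(values=[[0.5, 0.5]], weights=[1.0])

    def test_rejects_all_zero_weights(self):
        with pytest.raises(ValueError):
            ChoiceSet(values=[[0.5]], weights=[0.0])

    def test_rejects_bad_mask(self):
        with pytest.raises(ValueError):
            ChoiceSet(values=[[0.5]], weights=[1.0], available=[True, True])


class TestNetworkParamsValidation:
    @pytest.mark.parametrize("bad", [{"Q": 0.0}, {"Q": 1.2}, {"T_max": 0},
                                     {"s_P": -0.1}, {"l_A": -0.5}])
    def test_invalid_parameters(self, bad):
        kwargs = dict(s_P=1.0, l_P=0.0, s_A=0.0, l_A=0.0, Q=0.5)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            NetworkParams(**kwargs)

    def test_sampling_probs_must_normalize(self):
        with pytest.raises(ValueError):
            NetworkParams(s_P=1, l_P=0, s_A=0, l_A=0, Q=0.5,
                          sampling_probs=[0.5, 0.2])


class TestSimulateDecision:
    def test_lex_race_waits_for_top_attribute(self, two_by_two_set, rng):
        # memoryless acceptance with Q = max weight: only the best alternative
        # on the top attribute can cross, at the first sample of that attribute
        params = NetworkParams(s_P=0.0, l_P=0.0, s_A=1.0, l_A=1.0, Q=0.03)
        for _ in range(25):
            out = simulate_decision(two_by_two_set, params, rng,
                                    record_trajectory=True)
            assert out.chosen == 0
            first_top = int(np.argmax(out.sampled_attributes == 0)) + 1
            assert out.decision_time == first_top

    def test_single_available_alternative_always_chosen(self, rng):
        cs = ChoiceSet(values=[[0.4, 0.6]], weights=[0.01, 0.01])
        params = NetworkParams(s_P=1.0, l_P=0.0, s_A=0.0, l_A=0.0, Q=0.99)
        out = simulate_decision(cs, params, rng)
        assert out.chosen == 0

    def test_censoring_at_t_max(self, rng):
        cs = ChoiceSet(values=[[0.4], [0.5]], weights=[0.001])
        params = NetworkParams(s_P=0.0, l_P=0.0, s_A=0.0, l_A=0.0, Q=0.99, T_max=5)
        out = simulate_decision(cs, params, rng)
        assert out.censored and out.chosen is None
        assert out.decision_time == 5

    def test_unavailable_alternative_never_chosen(self, rng):
        cs = ChoiceSet(values=[[0.8, 0.2], [0.4, 0.9]], weights=[0.03, 0.015],
                       available=[True, False, True])
        params = NetworkParams(s_P=1.0, l_P=0.0, s_A=0.0, l_A=0.0, Q=0.9)
        for _ in range(10):
            out = simulate_decision(cs, params, rng)
            assert out.chosen in (0, 2)
        est = estimate_choice_probabilities(cs, params, 500, rng)
        assert est.probabilities[1] == 0.0

    def test_bit_reproducible_under_seed(self, two_by_two_set):
        params = NetworkParams(s_P=1.0, l_P=0.1, s_A=0.5, l_A=0.5, Q=0.6)
        a = simulate_decision(two_by_two_set, params,
                              np.random.default_rng(42), record_trajectory=True)
        b = simulate_decision(two_by_two_set, params,
                              np.random.default_rng(42), record_trajectory=True)
        assert a.chosen == b.chosen and a.decision_time == b.decision_time
        np.testing.assert_array_equal(a.trajectory, b.trajectory)

    def test_empty_choice_set_rejected(self):
        # a set with no available alternatives cannot even be constructed
        with pytest.raises(ValueError):
            ChoiceSet(values=np.empty((0, 1)), weights=[1.0],
                      available=[False, False])


class TestEstimateChoiceProbabilities:
    def test_probabilities_sum_to_one(self, two_by_two_set, rng):
        params = NetworkParams(s_P=1.0, l_P=0.0, s_A=1.0, l_A=1.0, Q=0.99)
        est = estimate_choice_probabilities(two_by_two_set, params, 2000, rng)
        assert est.probabilities.sum() == pytest.approx(1.0)

    def test_dominant_alternative_nearly_certain(self, rng):
        # strict dominance: the dominant row accumulates fastest every step
        cs = ChoiceSet(values=[[0.9, 0.9], [0.3, 0.2], [0.2, 0.3]],
                       weights=[0.03, 0.015])
        params = NetworkParams(s_P=1.0, l_P=0.0, s_A=0.0, l_A=0.0, Q=0.99)
        est = estimate_choice_probabilities(cs, params, 10_000, rng)
        assert est.probabilities[0] > 0.99

    def test_reproducible_and_seed_sensitive(self, two_by_two_set):
        params = NetworkParams(s_P=1.0, l_P=0.0, s_A=0.5, l_A=0.5, Q=0.5)
        a = estimate_choice_probabilities(two_by_two_set, params, 1000,
                                          np.random.default_rng(7))
        b = estimate_choice_probabilities(two_by_two_set, params, 1000,
                                          np.random.default_rng(7))
        np.testing.assert_array_equal(a.probabilities, b.probabilities)
        assert a.mean_decision_time == b.mean_decision_time

    def test_censored_trials_resolved_uniformly(self, rng):
        cs = ChoiceSet(values=[[0.4], [0.5]], weights=[0.001])
        params = NetworkParams(s_P=0.0, l_P=0.0, s_A=0.0, l_A=0.0, Q=0.99, T_max=3)
        est = estimate_choice_probabilities(cs, params, 2000, rng)
        assert est.censored_fraction == 1.0
        assert est.probabilities.sum() == pytest.approx(1.0)
        assert np.all(est.probabilities > 0.4)  # roughly uniform split

    def test_matches_single_trial_reference_distribution(self, rng):
        # the compiled batch kernel against the plain-python reference loop,
        # in a regime with leak and lateral inhibition active
        cs = ChoiceSet(values=[[0.8, 0.3], [0.5, 0.7]], weights=[0.4, 0.4])
        params = NetworkParams(s_P=0.6, l_P=0.3, s_A=0.2, l_A=0.1, Q=0.8)
        n = 4000
        ref = np.zeros(2)
        for _ in range(n):
            out = simulate_decision(cs, params, rng)
            ref[out.chosen] += 1
        ref /= n
        est = estimate_choice_probabilities(cs, params, n, rng)
        np.testing.assert_allclose(est.probabilities, ref, atol=0.035)

    def test_modal_choice_tie_is_none(self):
        from lcachoice import ChoiceProbabilities

        cp = ChoiceProbabilities(np.array([0.5, 0.5]), 1.0, 0.0, 10)
        assert cp.modal_choice() is None


def test_attribute_inputs_weights_and_caching_shape(two_by_two_set):
    params = NetworkParams(s_P=1.0, l_P=0.0, s_A=1.0, l_A=1.0, Q=0.99)
    V, profiles = attribute_inputs(two_by_two_set, params)
    assert V.shape == (2, 2)
    # identify-best sublayers: winner carries the full weight, loser nothing
    np.testing.assert_allclose(V[0], [0.03, 0.0], atol=1e-8)
    np.testing.assert_allclose(V[1], [0.0, 0.015], atol=1e-8)
    assert all(p.converged for p in profiles)
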