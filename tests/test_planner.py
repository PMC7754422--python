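import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from consnet.planner import (
    MAX_EXACT_NODES,
    PlannerError,
    build_transition_matrices,
    decode_state,
    encode_state,
    evaluate_policy_exact,
    greedy_policy,
    q_values,
    reward,
    value_iteration,
)
from conftest import make_model
from oracles import (
    finite_horizon_policy_value_oracle,
    finite_horizon_value_oracle,
)


class TestStateEncoding:
    def test_all_available_encodes_to_zero(self):
        assert encode_state([0] * 6) == 0

    def test_node_zero_is_least_significant(self):
        assert encode_state([1, 0, 0, 0, 0, 0]) == 1
        assert encode_state([0, 1, 0, 0, 0, 0]) == 3

    def test_roundtrip_exhaustive_six_nodes(self):
        for code in range(3**6):
            assert encode_state(decode_state(code, 6)) == code

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.integers(0, 2), min_size=1, max_size=8))
    def test_roundtrip_property(self, states):
        assert decode_state(encode_state(states), len(states)) == states

    def test_out_of_range_code_rejected(self):
        with pytest.raises(ValueError):
            decode_state(3**4, 4)

    def test_invalid_digit_rejected(self):
        with pytest.raises(ValueError):
            encode_state([0, 3])


class TestReward:
    def setup_method(self):
        # two sites, species 0 at site 0, species 1 everywhere
        self.model = make_model(2, [(0, 1)], [[1, 1], [0, 1]], cost=0.25)

    def test_nothing_reserved_no_intervention(self):
        assert reward(encode_state([0, 0]), 0, self.model) == 0.0

    def test_species_counted_once_across_reserves(self):
        s = encode_state([2, 2])
        assert reward(s, 0, self.model) == 2.0

    def test_intervention_cost_subtracted(self):
        s = encode_state([1, 1])
        assert reward(s, 1, self.model) == pytest.approx(-0.25)


class TestValueIteration:
    def test_single_node_certain_reservation_closed_form(self):
        """p_r=1, c=0, gamma=0.9: intervening yields gamma/(1-gamma) = 9."""
        model = make_model(1, [], [[1]], p_d=0.2, p_r=1.0, u_d=0.0, u_r=0.0,
                           gamma=0.9, cost=0.0)
        vi = value_iteration(model, tol=1e-10)
        policy = greedy_policy(model, vi)
        assert policy[0] == 1
        exact = evaluate_policy_exact(model, policy)
        assert exact[0] == pytest.approx(9.0, abs=1e-9)

    @pytest.mark.parametrize("corner", itertools.product((0.0, 0.5, 1.0), repeat=2))
    def test_two_node_instances_match_truncated_horizon_oracle(self, corner):
        u_d, u_r = corner
        gamma, cost = 0.8, 0.1
        incidence = [[1, 1, 0], [0, 1, 1]]
        edges = [(0, 1)]
        model = make_model(2, edges, incidence, p_d=0.5, p_r=0.5,
                           u_d=u_d, u_r=u_r, gamma=gamma, cost=cost)
        vi = value_iteration(model, tol=1e-8)
        horizon = 90  # gamma^90 * r_max/(1-gamma) << 1e-6
        oracle = finite_horizon_value_oracle(
            edges, np.array(incidence), 0.5, 0.5, u_d, u_r, gamma, cost, horizon
        )
        for states, v in oracle.items():
            assert vi.values[encode_state(list(states))] == pytest.approx(v, abs=1e-6)

    def test_residuals_contract_monotonically(self, two_node_model):
        mats = build_transition_matrices(two_node_model)
        v = np.zeros(two_node_model.n_states)
        residuals = []
        for _ in range(30):
            v_new = q_values(two_node_model, v, mats).max(axis=1)
            residuals.append(np.abs(v_new - v).max())
            v = v_new
        assert all(b <= a + 1e-12 for a, b in zip(residuals[1:], residuals[2:]))

    def test_nonconvergence_raises_with_residual(self, two_node_model):
        with pytest.raises(PlannerError, match="residual"):
            value_iteration(two_node_model, tol=1e-12, max_iter=3)

    def test_oversized_network_refused(self):
        n = MAX_EXACT_NODES + 1
        inc = np.eye(n, dtype=int)
        model = make_model(n, [(i, i + 1) for i in range(n - 1)], inc)
        with pytest.raises(PlannerError, match="exceeds"):
            build_transition_matrices(model)


class TestTransitionMatrices:
    def test_rows_are_distributions(self, three_node_star_model):
        for mat in build_transition_matrices(three_node_star_model):
            np.testing.assert_allclose(np.asarray(mat.sum(axis=1)).ravel(), 1.0)

    @pytest.mark.parametrize("corner", itertools.product((0.0, 0.5), repeat=4))
    def test_matrices_match_factored_oracle(self, corner):
        """Vectorized assembly equals the exhaustive product-measure oracle."""
        from oracles import joint_distribution_oracle

        p_d, p_r, u_d, u_r = corner
        edges = [(0, 1), (0, 2)]
        model = make_model(3, edges, np.eye(3, dtype=int),
                           p_d=p_d, p_r=p_r, u_d=u_d, u_r=u_r)
        mats = build_transition_matrices(model)
        for state in range(27):
            states = tuple(decode_state(state, 3))
            for action in range(4):
                want = joint_distribution_oracle(
                    states, action, edges, p_d, p_r, u_d, u_r
                )
                row = mats[action][state].toarray().ravel()
                dense = np.zeros(27)
                for nxt, p in want.items():
                    dense[encode_state(list(nxt))] = p
                np.testing.assert_allclose(row, dense, atol=1e-12)


class TestPolicies:
    def test_greedy_policy_noop_in_all_developed_state(self, two_node_model):
        vi = value_iteration(two_node_model, tol=1e-8)
        policy = greedy_policy(two_node_model, vi)
        assert policy[encode_state([1, 1])] == 0

    def test_greedy_policy_invariant_to_species_relabeling(self, rng):
        inc = (rng.random((3, 6)) < 0.5).astype(int)
        inc[0, inc.sum(axis=0) == 0] = 1
        edges = [(0, 1), (1, 2)]
        model = make_model(3, edges, inc, u_d=0.7, u_r=0.7)
        shuffled = make_model(3, edges, inc[:, rng.permutation(6)],
                              u_d=0.7, u_r=0.7)
        p1 = greedy_policy(model, value_iteration(model, tol=1e-9))
        p2 = greedy_policy(shuffled, value_iteration(shuffled, tol=1e-9))
        assert (p1 == p2).all()

    def test_evaluate_greedy_recovers_optimal_value(self, three_node_star_model):
        vi = value_iteration(three_node_star_model, tol=1e-9)
        policy = greedy_policy(three_node_star_model, vi)
        v_pi = evaluate_policy_exact(three_node_star_model, policy)
        np.testing.assert_allclose(v_pi, vi.values, atol=1e-6)

    def test_optimal_dominates_all_stationary_policies_two_nodes(self):
        """Optimality certificate by exhaustive policy enumeration."""
        model = make_model(2, [(0, 1)], [[1, 0], [0, 1]], u_d=0.6, u_r=0.6)
        vi = value_iteration(model, tol=1e-9)
        mats = build_transition_matrices(model)
        # enumerating all 3^9 policies is redundant: per-state argmax over
        # actions is independent, so checking every single-state deviation
        # from greedy covers every stationary policy by the policy
        # improvement theorem; still, sample a broad random set as well.
        greedy = greedy_policy(model, vi, mats)
        for s in range(9):
            for a in range(3):
                pol = greedy.copy()
                pol[s] = a
                v = evaluate_policy_exact(model, pol, mats)
                assert (v <= vi.values + 1e-6).all()
        rng = np.random.default_rng(0)
        for _ in range(200):
            pol = rng.integers(0, 3, size=9)
            v = evaluate_policy_exact(model, pol, mats)
            assert (v <= vi.values + 1e-6).all()

    def test_duplicating_a_species_cannot_decrease_value(self, rng):
        inc = np.array([[1, 0], [0, 1], [1, 1]])
        edges = [(0, 1), (1, 2)]
        base = make_model(3, edges, inc, u_d=0.5, u_r=0.5)
        dup = make_model(3, edges, np.hstack([inc, inc[:, :1]]), u_d=0.5, u_r=0.5)
        v_base = value_iteration(base, tol=1e-8).values
        v_dup = value_iteration(dup, tol=1e-8).values
        assert (v_dup >= v_base - 1e-6).all()

    def test_policy_evaluation_matches_monte_carlo(self, rng):
        """Exact linear-solve value agrees with simulated discounted returns."""
        from consnet.dynamics import simulate_trajectory

        model = make_model(3, [(0, 1), (0, 2)], np.eye(3, dtype=int),
                           u_d=0.6, u_r=0.6, gamma=0.8)
        vi = value_iteration(model, tol=1e-9)
        policy = greedy_policy(model, vi)
        v_exact = evaluate_policy_exact(model, policy)[0]
        horizon = 60  # 0.8^60 * V_max < 1e-4
        n_runs = 2000
        returns = np.empty(n_runs)
        for k in range(n_runs):
            traj = simulate_trajectory(model, policy, horizon, rng)
            returns[k] = sum(r * model.discount**t for t, (_, _, r) in enumerate(traj))
        se = returns.std(ddof=1) / np.sqrt(n_runs)
        assert abs(returns.mean() - v_exact) <= 3 * se + 1e-3
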