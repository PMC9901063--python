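"""Tests of policy evaluation, policy iteration, Q-learning, and baselines."""

import itertools

import numpy as np
import pytest

import regimen_rl as rr
from regimen_rl.errors import ConfigurationError
from regimen_rl.solvers import Policy, policy_evaluation_linear, value_iteration_q


def _one_state_mdp(r=1.0, gamma=0.3):
    return rr.TabularMDP(
        n_states=1, n_actions=1,
        transitions=np.ones((1, 1, 1)), rewards=np.full((1, 1), r),
        counts=np.ones((1, 1, 1)), gamma=gamma,
    )


class TestPolicyEvaluation:
    def test_geometric_series_value(self):
        v = rr.policy_evaluation(_one_state_mdp(), Policy(probs=np.ones((1, 1))))
        assert v[0] == pytest.approx(1.0 / 0.7, abs=1e-9)

    def test_zero_rewards_zero_value(self):
        v = rr.policy_evaluation(_one_state_mdp(r=0.0), Policy(probs=np.ones((1, 1))))
        assert v[0] == 0.0

    def test_matches_direct_linear_solve(self):
        for seed in range(10):
            gt = rr.random_mdp(3, 3, seed=seed)
            mdp = gt.to_tabular(0.3)
            pi = Policy(probs=gt.behavior_policy)
            iterative = rr.policy_evaluation(mdp, pi, tol=1e-12)
            direct = policy_evaluation_linear(mdp, pi)
            assert np.allclose(iterative.values, direct.values, atol=1e-8)

    def test_mismatched_policy_rejected(self):
        mdp = _one_state_mdp()
        with pytest.raises(ConfigurationError):
            rr.policy_evaluation(mdp, Policy(probs=np.full((2, 2), 0.5)))

    def test_nonstochastic_rows_rejected_at_construction(self):
        with pytest.raises(ConfigurationError):
            Policy(probs=np.full((2, 2), 0.4))


class TestPolicyIteration:
    def test_dominant_action_chosen_everywhere(self):
        gt = rr.dominance_mdp(n_states=4, seed=0)
        pol, _ = rr.policy_iteration(gt.to_tabular(0.3))
        assert np.all(pol.greedy_actions() == rr.ACTIONS.index("chei"))

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            S, A = int(rng.integers(2, 5)), int(rng.integers(2, 4))
            mdp = rr.random_mdp(S, A, seed=rng).to_tabular(0.3)
            _, v = rr.policy_iteration(mdp)
            best = np.full(S, -np.inf)
            for acts in itertools.product(range(A), repeat=S):
                vv = policy_evaluation_linear(mdp, Policy.deterministic(np.array(acts), A))
                best = np.maximum(best, vv.values)
            assert np.allclose(v.values, best, atol=1e-8)

    def test_value_monotone_across_improvement_cycles(self):
        mdp = rr.random_mdp(4, 3, seed=11).to_tabular(0.3)
        actions = np.zeros(4, dtype=int)
        prev = None
        for _ in range(20):
            pi = Policy.deterministic(actions, 3)
            v = rr.policy_evaluation(mdp, pi).values
            if prev is not None:
                assert np.all(v >= prev - 1e-9)
            prev = v
            q = mdp.rewards + 0.3 * np.einsum("sat,t->sa", mdp.transitions, v)
            new_actions = q.argmax(axis=1)
            if np.array_equal(new_actions, actions):
                break
            actions = new_actions

    def test_optimal_dominates_all_baselines_statewise(self):
        gt = rr.random_mdp(5, 4, seed=13)
        mdp = gt.to_tabular(0.3)
        _, v_opt = rr.policy_iteration(mdp)
        for pol in (
            Policy(probs=gt.behavior_policy),
            rr.zero_policy(5, 4),
            rr.random_policy(5, 4),
        ):
            v = rr.policy_evaluation(mdp, pol)
            assert np.all(v_opt.values >= v.values - 1e-9)


class TestQLearning:
    def _single_step(self):
        return rr.TrajectorySet(
            (
                rr.Trajectory(
                    patient_id="A",
                    states=np.array([0]), actions=np.array([1]),
                    rewards=np.array([-2.0]), next_states=np.array([2]),
                ),
            )
        )

    def test_single_terminal_update_by_hand(self):
        qt = rr.q_learning(self._single_step(), 3, 2, alpha=0.05, gamma=0.3, epochs=1, seed=0)
        assert qt.q[0, 1] == pytest.approx(-0.1)
        assert qt.n_updates == 1

    def test_zero_epochs_keeps_zero_table(self):
        qt = rr.q_learning(self._single_step(), 3, 2, epochs=0)
        assert np.all(qt.q == 0.0)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.1])
    def test_invalid_alpha_rejected(self, alpha):
        with pytest.raises(ConfigurationError):
            rr.q_learning(self._single_step(), 3, 2, alpha=alpha)

    def test_converges_to_planning_policy_on_covered_toy(self, toy_deterministic_mdp):
        trajs = rr.generate_trajectories(toy_deterministic_mdp, 5, horizon=600, seed=2)
        qt = rr.q_learning(trajs, 5, 3, alpha=0.05, gamma=0.3, epochs=60, seed=3)
        mdp = toy_deterministic_mdp.to_tabular(0.3)
        pol_pi, _ = rr.policy_iteration(mdp)
        assert np.array_equal(rr.greedy_policy(qt).greedy_actions(), pol_pi.greedy_actions())
        qstar = value_iteration_q(mdp, tol=1e-10)
        assert np.max(np.abs(qt.q - qstar)) < 0.05


class TestGreedyPolicy:
    def test_argmax_row(self):
        qt = rr.QTable(q=np.array([[0.0, 5.0, 0.0, 0.0, 0.0, 0.0]]), alpha=0.05, n_updates=1)
        pol = rr.greedy_policy(qt)
        assert pol.probs[0, 1] == 1.0

    def test_all_equal_row_ties_to_no_drugs(self):
        qt = rr.QTable(q=np.zeros((2, 6)), alpha=0.05, n_updates=0)
        assert np.all(rr.greedy_policy(qt).greedy_actions() == 0)


class TestClinicianPolicy:
    def test_single_action_mdp_reproduces_behavior(self):
        mdp = _one_state_mdp()
        behavior = Policy(probs=np.ones((1, 1)), role="behavior")
        clin = rr.clinician_policy(mdp, behavior)
        assert np.allclose(clin.probs, behavior.probs)
        assert clin.role == "clinician"

    def test_two_state_improvement_by_hand(self):
        # two states, two actions; action 1 pays +1 in both states and keeps
        # you in place, action 0 pays 0 and flips state. uniform behavior.
        P = np.zeros((2, 2, 2))
        P[0, 0, 1] = P[1, 0, 0] = 1.0
        P[0, 1, 0] = P[1, 1, 1] = 1.0
        R = np.array([[0.0, 1.0], [0.0, 1.0]])
        mdp = rr.TabularMDP(2, 2, P, R, np.zeros_like(P), gamma=0.3)
        behavior = Policy(probs=np.full((2, 2), 0.5))
        # v_b = 0.5 / (1 - 0.3) in both states by symmetry; greedy backup picks a=1
        clin = rr.clinician_policy(mdp, behavior)
        assert np.all(clin.greedy_actions() == 1)

    def test_one_step_improvement_weakly_dominates_behavior(self):
        for seed in range(5):
            gt = rr.random_mdp(4, 3, seed=seed)
            mdp = gt.to_tabular(0.3)
            behavior = Policy(probs=gt.behavior_policy)
            clin = rr.clinician_policy(mdp, behavior)
            v_b = rr.policy_evaluation(mdp, behavior).values
            v_c = rr.policy_evaluation(mdp, clin).values
            assert np.all(v_c >= v_b - 1e-9)


class TestBehaviorAndBaselines:
    def _trajs(self, pairs):
        return rr.TrajectorySet(
            tuple(
                rr.Trajectory(
                    patient_id=str(i),
                    states=np.array([s]), actions=np.array([a]),
                    rewards=np.array([0.0]), next_states=np.array([0]),
                )
                for i, (s, a) in enumerate(pairs)
            )
        )

    def test_empirical_frequencies(self):
        trajs = self._trajs([(0, 1)] * 3 + [(0, 2)])
        pol = rr.behavior_policy_empirical(trajs, 2, 3, smoothing=0.0)
        assert pol.probs[0, 1] == pytest.approx(0.75)
        assert pol.probs[0, 2] == pytest.approx(0.25)

    def test_unvisited_state_is_uniform(self):
        pol = rr.behavior_policy_empirical(self._trajs([(0, 0)]), 2, 6)
        assert np.allclose(pol.probs[1], 1 / 6)

    def test_heavy_smoothing_approaches_uniform(self):
        trajs = self._trajs([(0, 1)] * 10)
        pol = rr.behavior_policy_empirical(trajs, 1, 4, smoothing=1e9)
        assert np.allclose(pol.probs[0], 0.25, atol=1e-6)

    def test_zero_policy_rows(self):
        pol = rr.zero_policy(3)
        assert np.allclose(pol.probs[:, 0], 1.0)
        assert np.allclose(pol.probs.sum(axis=1), 1.0)

    def test_random_policy_rows(self):
        pol = rr.random_policy(3, 6)
        assert np.allclose(pol.probs, 1 / 6)
        assert np.allclose(pol.probs.sum(axis=1), 1.0)
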