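"""Policies, value functions, and tabular planning/learning algorithms.

Implements exact policy evaluation and policy iteration on an estimated
tabular MDP, offline tabular Q-learning by replay of logged transitions, the
one-step-improved "clinician" policy, the empirical behavior policy, and the
zero/random baselines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .mdp_builder import N_ACTIONS, TabularMDP, TrajectorySet

_ROLES = ("optimal_pi", "optimal_q", "clinician", "behavior", "zero", "random")


@dataclass(frozen=True)
class Policy:
    """Per-state action distribution π(a|s) with a role tag."""

    probs: np.ndarray  # (S, A)
    role: str = "behavior"

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2:
            raise ValueError("policy probabilities must be a (states, actions) table")
        if np.any(p < 0) or not np.allclose(p.sum(axis=1), 1.0, atol=1e-12):
            raise ConfigurationError("each policy row must be a probability distribution")
        object.__setattr__(self, "probs", p)

    @property
    def n_states(self) -> int:
        return self.probs.shape[0]

    @property
    def n_actions(self) -> int:
        return self.probs.shape[1]

    @classmethod
    def deterministic(cls, actions: np.ndarray, n_actions: int, role: str = "behavior") -> "Policy":
        """Probability-1 policy from a per-state action vector."""
        actions = np.asarray(actions, dtype=int)
        p = np.zeros((len(actions), n_actions))
        p[np.arange(len(actions)), actions] = 1.0
        return cls(probs=p, role=role)

    def greedy_actions(self) -> np.ndarray:
        """Most probable action per state (ties to the lowest action id)."""
        return self.probs.argmax(axis=1)


@dataclass(frozen=True)
class ValueFunction:
    """State values v(s)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("state values must be finite")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, s: int) -> float:
        return float(self.values[s])


@dataclass(frozen=True)
class QTable:
    """State-action values with the learning rate that produced them."""

    q: np.ndarray  # (S, A)
    alpha: float
    n_updates: int


def _validate_policy_for(mdp: TabularMDP, pi: Policy) -> None:
    if pi.probs.shape != (mdp.n_states, mdp.n_actions):
        raise ConfigurationError(
            f"policy shape {pi.probs.shape} does not match MDP "
            f"({mdp.n_states} states, {mdp.n_actions} actions)"
        )


def policy_evaluation(mdp: TabularMDP, pi: Policy, tol: float = 1e-10) -> ValueFunction:
    """Iterative evaluation of v_π to a Bellman residual below ``tol``.

    Sweeps v ← R_π + γ P_π v until ‖v − (R_π + γ P_π v)‖_∞ < tol.  For γ<1
    this is a contraction, so the sweep always terminates.
    """
    _validate_policy_for(mdp, pi)
    r_pi = (pi.probs * mdp.rewards).sum(axis=1)
    p_pi = np.einsum("sa,sat->st", pi.probs, mdp.transitions)
    v = np.zeros(mdp.n_states)
    while True:
        v_next = r_pi + mdp.gamma * p_pi @ v
        if np.max(np.abs(v_next - v)) < tol:
            return ValueFunction(values=v_next)
        v = v_next


def policy_evaluation_linear(mdp: TabularMDP, pi: Policy) -> ValueFunction:
    """Direct linear solve v = (I − γP_π)^{-1} R_π (exact, used as an oracle)."""
    _validate_policy_for(mdp, pi)
    r_pi = (pi.probs * mdp.rewards).sum(axis=1)
    p_pi = np.einsum("sa,sat->st", pi.probs, mdp.transitions)
    v = np.linalg.solve(np.eye(mdp.n_states) - mdp.gamma * p_pi, r_pi)
    return ValueFunction(values=v)


def _q_from_values(mdp: TabularMDP, v: np.ndarray) -> np.ndarray:
    """One Bellman backup: Q(s,a) = R(s,a) + γ Σ_{s'} P(s'|s,a) v(s')."""
    return mdp.rewards + mdp.gamma * np.einsum("sat,t->sa", mdp.transitions, v)


def policy_iteration(mdp: TabularMDP, tol: float = 1e-10) -> tuple[Policy, ValueFunction]:
    """Exact policy iteration: alternate evaluation and greedy improvement.

    Returns a deterministic policy that is greedy with respect to its own
    value function, together with that value function.  Ties in the argmax
    break to the lowest action id, so the fixed point is unique and the loop
    terminates.
    """
    actions = np.zeros(mdp.n_states, dtype=int)
    for _ in range(mdp.n_actions ** mdp.n_states + 1):
        pi = Policy.deterministic(actions, mdp.n_actions, role="optimal_pi")
        v = policy_evaluation(mdp, pi, tol=tol)
        improved = _q_from_values(mdp, v.values).argmax(axis=1)
        if np.array_equal(improved, actions):
            return pi, v
        actions = improved
    raise RuntimeError("policy iteration failed to converge")  # pragma: no cover


def value_iteration_q(mdp: TabularMDP, tol: float = 1e-10) -> np.ndarray:
    """Optimal Q* by value iteration; used only as a planning oracle."""
    q = np.zeros((mdp.n_states, mdp.n_actions))
    while True:
        q_next = _q_from_values(mdp, q.max(axis=1))
        if np.max(np.abs(q_next - q)) < tol:
            return q_next
        q = q_next


def q_learning(
    trajs: TrajectorySet,
    n_states: int,
    n_actions: int = N_ACTIONS,
    alpha: float = 0.05,
    gamma: float = 0.3,
    epochs: int = 50,
    seed: int = 0,
) -> QTable:
    """Offline tabular Q-learning by replay of the logged transitions.

    Each epoch shuffles the pooled steps (under ``seed``) and applies
    Q(s,a) ← Q(s,a) + α (r + γ max_{a'} Q(s',a') − Q(s,a)); the final step of
    a trajectory uses the target r alone.  The learner never consults the
    estimated transition tensor — it is model-free by construction.
    """
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError(f"alpha must lie in (0, 1), got {alpha}")
    if not 0.0 <= gamma < 1.0:
        raise ConfigurationError(f"gamma must lie in [0, 1), got {gamma}")
    if epochs < 0:
        raise ConfigurationError("epochs must be nonnegative")
    if trajs.n_steps < 1:
        raise ValueError("at least one logged step is required")
    s_arr, a_arr, r_arr, ns_arr, term_arr = trajs.steps()
    # plain-python replay loop: list indexing is markedly faster than numpy
    # scalar indexing for this access pattern
    steps = list(zip(s_arr.tolist(), a_arr.tolist(), r_arr.tolist(), ns_arr.tolist(), term_arr.tolist()))
    q = [[0.0] * n_actions for _ in range(n_states)]
    rng = np.random.default_rng(seed)
    order = np.arange(len(steps))
    n_updates = 0
    for _ in range(epochs):
        rng.shuffle(order)
        for idx in order.tolist():
            s, a, r, ns, term = steps[idx]
            target = r if term else r + gamma * max(q[ns])
            q[s][a] += alpha * (target - q[s][a])
            n_updates += 1
    return QTable(q=np.asarray(q, dtype=float), alpha=alpha, n_updates=n_updates)


def greedy_policy(q: QTable) -> Policy:
    """Deterministic argmax policy from a Q-table (ties → lowest action id)."""
    actions = np.asarray(q.q).argmax(axis=1)
    return Policy.deterministic(actions, np.asarray(q.q).shape[1], role="optimal_q")


def behavior_policy_empirical(
    trajs: TrajectorySet,
    n_states: int,
    n_actions: int = N_ACTIONS,
    smoothing: float = 0.0,
) -> Policy:
    """Empirical behavior policy π_b(a|s) from logged action frequencies.

    Additive smoothing (if any) guarantees coverage of every action in
    visited states; states never visited in the log get the uniform
    distribution.
    """
    if smoothing < 0:
        raise ConfigurationError("smoothing must be nonnegative")
    if trajs.n_steps < 1:
        raise ValueError("at least one logged step is required")
    s, a, _, _, _ = trajs.steps()
    counts = np.zeros((n_states, n_actions), dtype=float)
    np.add.at(counts, (s, a), 1.0)
    totals = counts.sum(axis=1)
    probs = np.full((n_states, n_actions), 1.0 / n_actions)
    visited = totals > 0
    probs[visited] = (counts[visited] + smoothing) / (
        totals[visited, None] + smoothing * n_actions
    )
    return Policy(probs=probs, role="behavior")


def clinician_policy(mdp: TabularMDP, behavior: Policy) -> Policy:
    """Single evaluation-improvement cycle on the empirical behavior policy.

    Evaluates the behavior policy in the estimated MDP and applies one greedy
    improvement step.  By the policy-improvement theorem the result weakly
    dominates the behavior policy under the same MDP; it serves as the
    data-driven stand-in for the treating clinicians' strategy.
    """
    _validate_policy_for(mdp, behavior)
    v = policy_evaluation(mdp, behavior)
    actions = _q_from_values(mdp, v.values).argmax(axis=1)
    return Policy.deterministic(actions, mdp.n_actions, role="clinician")


def zero_policy(n_states: int, n_actions: int = N_ACTIONS) -> Policy:
    """Prescribe no drugs (action 0) in every state."""
    if n_states < 1:
        raise ConfigurationError("n_states must be at least 1")
    p = np.zeros((n_states, n_actions))
    p[:, 0] = 1.0
    return Policy(probs=p, role="zero")


def random_policy(n_states: int, n_actions: int = N_ACTIONS) -> Policy:
    """Prescribe uniformly at random in every state."""
    if n_states < 1:
        raise ConfigurationError("n_states must be at least 1")
    return Policy(probs=np.full((n_states, n_actions), 1.0 / n_actions), role="random")
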