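"""Synthetic longitudinal cohorts and ground-truth MDPs.

Every downstream stage (state discretization, MDP estimation, planning,
off-policy evaluation) is exercised against data with known generative
dynamics, because the clinical registry the schema is modelled on is
access-restricted.  Two generators are provided:

* :func:`generate_cohort` — a visit-level table of synthetic AD patients.
  MMSE evolves as a noisy action-dependent random walk clipped to [0, 30];
  the other assessments are noisy affine functions of MMSE, which gives the
  state tree the correlation structure it exploits.  Medication frequencies
  default to those of a large observational AD cohort (supplements and
  "no drugs" dominate; ChEIs, memantine, the combination and
  antihypertensives are comparatively rare).
* :func:`generate_trajectories` — (s, a, r) trajectories rolled out from an
  explicit tabular :class:`GroundTruthMDP`, for estimator recovery tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .mdp_builder import (
    ACTIONS,
    ActionVocabulary,
    N_ACTIONS,
    TabularMDP,
    Trajectory,
    TrajectorySet,
)

#: Default per-visit medication class probabilities, matching the relative
#: frequencies reported for a 1,736-patient observational cohort
#: (~10,082 visits: supplements/other and no-drugs each ≈45%, ChEI ≈4%,
#: antihypertensive ≈2.7%, memantine ≈1.7%, ChEI+memantine ≈1.4%).
DEFAULT_ACTION_PROBABILITIES: tuple[float, ...] = (
    0.4464, 0.0415, 0.0175, 0.0268, 0.0144, 0.4534,
)

#: Default mean MMSE change per visit (points) under each action class.
DEFAULT_ACTION_EFFECT: dict[str, float] = {
    "no_drugs": -1.2,
    "chei": -0.5,
    "memantine": -0.6,
    "antihypertensive": -0.9,
    "chei_plus_memantine": -0.4,
    "supplements_other": -1.0,
}

DEFAULT_COMORBIDITY_PREVALENCE: dict[str, float] = {
    "hypertension": 0.30,
    "depression": 0.28,
}

_ASSESSMENT_COLUMNS = (
    "mmse", "adas13", "ravlt_immediate", "ravlt_learning", "cdrsb", "moca", "fdg",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic visit-table generator.

    ``action_effect`` maps action names to the mean MMSE change (points) per
    visit interval; ``noise_sd`` is the standard deviation of the Gaussian
    innovation on that change.  ``action_probabilities`` is the per-visit
    prescription distribution over the six action classes (tilted toward
    antihypertensives for hypertensive patients).
    """

    n_patients: int = 1736
    visit_interval_months: float = 6.0
    mean_visits: float = 6.42
    comorbidity_prevalence: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMORBIDITY_PREVALENCE)
    )
    action_effect: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ACTION_EFFECT)
    )
    action_probabilities: tuple[float, ...] = DEFAULT_ACTION_PROBABILITIES
    noise_sd: float = 1.5
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be at least 1")
        if self.visit_interval_months <= 0:
            raise ConfigurationError("visit_interval_months must be positive")
        if self.mean_visits <= 0:
            raise ConfigurationError("mean_visits must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigurationError("missing_rate must lie in [0, 1]")
        for name, p in self.comorbidity_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"prevalence of {name!r} must lie in [0, 1]")
        probs = np.asarray(self.action_probabilities, dtype=float)
        if probs.shape != (N_ACTIONS,) or np.any(probs < 0) or not math.isclose(
            probs.sum(), 1.0, abs_tol=1e-9
        ):
            raise ConfigurationError(
                "action_probabilities must be a distribution over the six actions"
            )
        unknown = set(self.action_effect) - set(ACTIONS)
        if unknown:
            raise ConfigurationError(f"unknown action name(s) in action_effect: {sorted(unknown)}")
        if self.seed < 0:
            raise ConfigurationError("seed must be a nonnegative integer")


@dataclass(frozen=True)
class GroundTruthMDP:
    """An explicit tabular MDP used to roll out trajectories with known truth."""

    n_states: int
    n_actions: int
    transitions: np.ndarray      # (S, A, S)
    rewards: np.ndarray          # (S, A) expected reward
    behavior_policy: np.ndarray  # (S, A)

    def __post_init__(self) -> None:
        P = np.asarray(self.transitions, dtype=float)
        B = np.asarray(self.behavior_policy, dtype=float)
        if P.shape != (self.n_states, self.n_actions, self.n_states):
            raise ConfigurationError("transition tensor has wrong shape")
        if B.shape != (self.n_states, self.n_actions):
            raise ConfigurationError("behavior policy has wrong shape")
        if np.any(P < 0) or not np.allclose(P.sum(axis=2), 1.0, atol=1e-12):
            raise ConfigurationError("each (s, a) transition row must sum to 1")
        if np.any(B < 0) or not np.allclose(B.sum(axis=1), 1.0, atol=1e-12):
            raise ConfigurationError("each behavior-policy row must sum to 1")
        object.__setattr__(self, "transitions", P)
        object.__setattr__(self, "rewards", np.asarray(self.rewards, dtype=float))
        object.__setattr__(self, "behavior_policy", B)

    def to_tabular(self, gamma: float = 0.3) -> TabularMDP:
        """View as an estimated-MDP container so the exact solvers apply."""
        return TabularMDP(
            n_states=self.n_states,
            n_actions=self.n_actions,
            transitions=self.transitions.copy(),
            rewards=self.rewards.copy(),
            counts=np.zeros_like(self.transitions),
            gamma=gamma,
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_states": self.n_states,
                "n_actions": self.n_actions,
                "transitions": self.transitions.tolist(),
                "rewards": self.rewards.tolist(),
                "behavior_policy": self.behavior_policy.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthMDP":
        d = json.loads(text)
        return cls(
            n_states=int(d["n_states"]),
            n_actions=int(d["n_actions"]),
            transitions=np.asarray(d["transitions"], dtype=float),
            rewards=np.asarray(d["rewards"], dtype=float),
            behavior_policy=np.asarray(d["behavior_policy"], dtype=float),
        )


def _blank(rng: np.random.Generator, value: float, rate: float) -> float:
    return np.nan if rate > 0 and rng.random() < rate else value


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a synthetic visit table with known latent dynamics.

    Each patient gets an independent random stream derived from
    ``(config.seed, patient index)``, so cohorts are reproducible and stable
    under reordering.  Visit counts are 1 + Poisson(mean_visits − 1); the
    MMSE random walk is clipped to [0, 30] and rounded to integers; ADAS13
    and the other assessments are decreasing/increasing affine functions of
    MMSE plus noise; comorbidity flags are constant within a patient; a
    fraction ``missing_rate`` of assessment cells is blanked uniformly at
    random (identifiers, visit months and medications are never blanked).
    """
    vocab = ActionVocabulary.default()
    effects = np.array(
        [config.action_effect.get(name, DEFAULT_ACTION_EFFECT[name]) for name in ACTIONS]
    )
    base_probs = np.asarray(config.action_probabilities, dtype=float)
    p_hyp = float(config.comorbidity_prevalence.get("hypertension", 0.0))
    p_dep = float(config.comorbidity_prevalence.get("depression", 0.0))
    # pre-draw a representative name per action (deterministic per action)
    action_names: list[list[str]] = [vocab.names_for(a) for a in range(N_ACTIONS)]

    rows: list[tuple] = []
    for i in range(config.n_patients):
        rng = np.random.default_rng((config.seed, i))
        pid = f"P{i:05d}"
        n_visits = 1 + (rng.poisson(config.mean_visits - 1.0) if config.mean_visits > 1 else 0)
        age0 = float(np.clip(rng.normal(74.0, 7.0), 55.0, 92.0))
        hyp = bool(rng.random() < p_hyp)
        dep = bool(rng.random() < p_dep)
        probs = base_probs
        if hyp:
            probs = base_probs.copy()
            probs[ACTIONS.index("antihypertensive")] += 0.15
            probs = probs / probs.sum()
        mmse = float(np.clip(round(rng.normal(23.5, 3.5)), 0, 30))
        for t in range(n_visits):
            month = int(round(t * config.visit_interval_months))
            age = age0 + month / 12.0
            a = int(rng.choice(N_ACTIONS, p=probs))
            if a == 0:
                medication = ""
            elif ACTIONS[a] == "chei_plus_memantine":
                medication = (
                    f"{rng.choice(action_names[ACTIONS.index('chei')])}; "
                    f"{rng.choice(action_names[ACTIONS.index('memantine')])}"
                )
            else:
                medication = str(rng.choice(action_names[a]))
            adas13 = float(np.clip(72.0 - 2.0 * mmse + rng.normal(0.0, 3.0), 0.0, 85.0))
            ravlt_imm = float(np.clip(1.6 * mmse - 8.0 + rng.normal(0.0, 4.0), 0.0, 75.0))
            ravlt_lrn = float(np.clip(0.25 * mmse - 1.5 + rng.normal(0.0, 1.2), -5.0, 14.0))
            cdrsb = float(np.clip(0.45 * (30.0 - mmse) + rng.normal(0.0, 1.0), 0.0, 18.0))
            moca = float(np.clip(mmse - 2.5 + rng.normal(0.0, 1.5), 0.0, 30.0))
            fdg = float(np.clip(0.9 + 0.015 * mmse + rng.normal(0.0, 0.08), 0.3, 1.8))
            r = config.missing_rate
            rows.append(
                (
                    pid,
                    month,
                    round(age, 1),
                    _blank(rng, mmse, r),
                    _blank(rng, round(adas13, 1), r),
                    _blank(rng, round(ravlt_imm, 1), r),
                    _blank(rng, round(ravlt_lrn, 1), r),
                    _blank(rng, round(cdrsb, 1), r),
                    _blank(rng, round(moca, 1), r),
                    _blank(rng, round(fdg, 3), r),
                    medication,
                    int(hyp),
                    int(dep),
                )
            )
            # latent progression to the next visit
            mmse = float(np.clip(round(mmse + effects[a] + rng.normal(0.0, config.noise_sd)), 0, 30))
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "visit_month", "age", "mmse", "adas13",
            "ravlt_immediate", "ravlt_learning", "cdrsb", "moca", "fdg",
            "medication", "hypertension", "depression",
        ],
    )


def generate_trajectories(
    mdp: GroundTruthMDP, n_trajectories: int, horizon: int, seed: int = 0
) -> TrajectorySet:
    """Roll out trajectories from a ground-truth MDP under its behavior policy.

    Initial states are uniform over the state space; actions are drawn from
    the behavior policy and next states from the transition tensor; the step
    reward is the expected reward R(s, a) (the generator's randomness lies in
    the action and transition draws).
    """
    if horizon < 1:
        raise ConfigurationError("horizon must be at least 1")
    if n_trajectories < 1:
        raise ConfigurationError("n_trajectories must be at least 1")
    rng = np.random.default_rng(seed)
    n, S = n_trajectories, mdp.n_states
    cum_b = np.cumsum(mdp.behavior_policy, axis=1)
    cum_p = np.cumsum(mdp.transitions, axis=2)
    s = rng.integers(0, S, size=n)
    states = np.empty((n, horizon), dtype=np.int64)
    actions = np.empty((n, horizon), dtype=np.int64)
    rewards = np.empty((n, horizon), dtype=float)
    next_states = np.empty((n, horizon), dtype=np.int64)
    for t in range(horizon):
        u = rng.random(n)
        a = (cum_b[s] > u[:, None]).argmax(axis=1)
        u2 = rng.random(n)
        ns = (cum_p[s, a] > u2[:, None]).argmax(axis=1)
        states[:, t] = s
        actions[:, t] = a
        rewards[:, t] = mdp.rewards[s, a]
        next_states[:, t] = ns
        s = ns
    return TrajectorySet(
        tuple(
            Trajectory(
                patient_id=f"T{i:06d}",
                states=states[i],
                actions=actions[i],
                rewards=rewards[i],
                next_states=next_states[i],
            )
            for i in range(n)
        )
    )


def random_mdp(
    n_states: int,
    n_actions: int,
    seed: int | np.random.Generator = 0,
    reward_scale: float = 1.0,
    behavior: str = "dirichlet",
) -> GroundTruthMDP:
    """A random dense MDP: Dirichlet(1) transition rows, Gaussian rewards.

    ``behavior`` selects the logging policy: ``"uniform"`` or a Dirichlet(1)
    draw per state.  Useful for estimator recovery and planner stress tests.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    P = rng.dirichlet(np.ones(n_states), size=(n_states, n_actions))
    R = rng.normal(0.0, reward_scale, size=(n_states, n_actions))
    if behavior == "uniform":
        B = np.full((n_states, n_actions), 1.0 / n_actions)
    else:
        B = rng.dirichlet(np.ones(n_actions), size=n_states)
    return GroundTruthMDP(
        n_states=n_states, n_actions=n_actions, transitions=P, rewards=R, behavior_policy=B
    )


#: Action effects for the dominance scenario: ChEI strictly best, no-drugs
#: strictly worst, the other classes in between.
DOMINANCE_ACTION_EFFECT: dict[str, float] = {
    "no_drugs": -2.0,
    "chei": 1.0,
    "memantine": -0.5,
    "antihypertensive": -1.0,
    "chei_plus_memantine": 0.5,
    "supplements_other": -1.5,
}


def dominance_mdp(n_states: int = 5, seed: int = 0) -> GroundTruthMDP:
    """A ground-truth MDP in which one drug class strictly dominates.

    Rewards depend on the action only (the per-visit MMSE change each class
    yields), so exact policy values order cleanly: the greedy planner picks
    ChEI everywhere, the no-drugs (zero) policy is worst, and a behavior
    policy tilted toward the effective classes sits between the uniform
    random policy and the optimum.
    """
    rng = np.random.default_rng(seed)
    effects = np.array([DOMINANCE_ACTION_EFFECT[name] for name in ACTIONS])
    P = rng.dirichlet(np.ones(n_states), size=(n_states, N_ACTIONS))
    R = np.tile(effects, (n_states, 1))
    B = np.tile(np.array([0.10, 0.30, 0.15, 0.15, 0.20, 0.10]), (n_states, 1))
    return GroundTruthMDP(
        n_states=n_states, n_actions=N_ACTIONS, transitions=P, rewards=R, behavior_policy=B
    )
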