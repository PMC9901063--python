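"""Actions, trajectories, and tabular MDP estimation.

Medication strings are collapsed into six action classes (no drugs, ChEIs,
memantine, antihypertensives, ChEI+memantine, supplements/other), per-visit
MMSE differences become rewards, consecutive assigned visits become
state-action-reward trajectories, and the tabular Markov decision process
(transition tensor, expected reward table) is estimated by counting.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, SchemaError

logger = logging.getLogger(__name__)

#: The six action classes, in canonical id order.  ``no_drugs`` is action 0
#: by convention (the zero policy prescribes it everywhere).
ACTIONS: tuple[str, ...] = (
    "no_drugs",
    "chei",
    "memantine",
    "antihypertensive",
    "chei_plus_memantine",
    "supplements_other",
)
N_ACTIONS = len(ACTIONS)

_SPLIT_RE = re.compile(r"[;,+/]")


@dataclass(frozen=True)
class ActionVocabulary:
    """Maps free-text drug names to the six-action vocabulary.

    ``lexicon`` maps a normalized drug name to an action *name* (one of
    :data:`ACTIONS` except the combination class, which arises only from
    co-occurrence).  Unknown names fall back to ``supplements_other``.
    """

    lexicon: Mapping[str, str] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "ActionVocabulary":
        """Load the bundled medication lexicon."""
        text = resources.files("regimen_rl.data").joinpath("medications.yaml").read_text()
        raw = yaml.safe_load(text)
        lex: dict[str, str] = {}
        for action_name, names in raw.items():
            if action_name not in ACTIONS:
                raise ConfigurationError(f"unknown action class in lexicon: {action_name}")
            for name in names:
                lex[str(name).strip().lower()] = action_name
        return cls(lexicon=lex)

    def names_for(self, action: int | str) -> list[str]:
        """All lexicon entries belonging to an action class."""
        name = ACTIONS[action] if isinstance(action, int) else action
        return sorted(k for k, v in self.lexicon.items() if v == name)


def action_id(name: str) -> int:
    return ACTIONS.index(name)


def map_action(medication: str | float | None, vocab: ActionVocabulary) -> int:
    """Map a free-text medication entry to an action id.

    Compound entries are split on separators; if both a ChEI and memantine
    occur the combination class wins, otherwise the most AD-specific class
    present does (ChEI > memantine > antihypertensive > supplements).  An
    empty entry means no drugs; unknown names are logged and fall back to
    ``supplements_other`` — the lookup is total.
    """
    if medication is None or (isinstance(medication, float) and np.isnan(medication)):
        return action_id("no_drugs")
    text = str(medication).strip()
    if not text:
        return action_id("no_drugs")
    classes: set[str] = set()
    for token in _SPLIT_RE.split(text):
        token = token.strip().lower()
        if not token:
            continue
        cls = vocab.lexicon.get(token)
        if cls is None:
            logger.debug("unknown medication %r -> supplements_other", token)
            cls = "supplements_other"
        classes.add(cls)
    if not classes:
        return action_id("no_drugs")
    if "chei" in classes and "memantine" in classes:
        return action_id("chei_plus_memantine")
    for name in ("chei", "memantine", "antihypertensive"):
        if name in classes:
            return action_id(name)
    return action_id("supplements_other")


@dataclass(frozen=True)
class Trajectory:
    """One contiguous (state, action, reward) segment for a patient.

    ``states[t]`` is the state at step t, ``next_states[t]`` the state at the
    following visit; the final step of a trajectory is treated as terminal by
    the offline learners.  Rewards are per-visit MMSE differences.
    """

    patient_id: str
    states: np.ndarray
    actions: np.ndarray
    rewards: np.ndarray
    next_states: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.states)
        if n < 1:
            raise ValueError("trajectory must contain at least one step")
        if not (len(self.actions) == len(self.rewards) == len(self.next_states) == n):
            raise ValueError("trajectory arrays must share one length")
        if not np.all(np.isfinite(self.rewards)):
            raise ValueError("rewards must be finite")

    def __len__(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class TrajectorySet:
    """A collection of trajectories, the unit of MDP estimation and OPE."""

    trajectories: tuple[Trajectory, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "trajectories", tuple(self.trajectories))

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self) -> Iterator[Trajectory]:
        return iter(self.trajectories)

    @property
    def n_steps(self) -> int:
        return sum(len(t) for t in self.trajectories)

    def steps(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Concatenated (s, a, r, s', terminal) arrays over all steps.

        ``terminal`` marks the last step of each trajectory; offline learners
        do not bootstrap past it.
        """
        s = np.concatenate([t.states for t in self.trajectories])
        a = np.concatenate([t.actions for t in self.trajectories])
        r = np.concatenate([t.rewards for t in self.trajectories])
        ns = np.concatenate([t.next_states for t in self.trajectories])
        term = np.zeros(len(s), dtype=bool)
        pos = 0
        for t in self.trajectories:
            pos += len(t)
            term[pos - 1] = True
        return s, a, r, ns, term

    def subset(self, patient_ids: Iterable[str]) -> "TrajectorySet":
        keep = set(patient_ids)
        return TrajectorySet(tuple(t for t in self.trajectories if t.patient_id in keep))

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: one row per (patient, step)."""
        rows = []
        for t in self.trajectories:
            for k in range(len(t)):
                rows.append((t.patient_id, k, int(t.states[k]), int(t.actions[k]), float(t.rewards[k])))
        return pd.DataFrame(rows, columns=["patient_id", "step", "state", "action", "reward"])


@dataclass(frozen=True)
class TabularMDP:
    """Estimated finite MDP: P(s'|s,a), R(s,a), visit counts, discount γ."""

    n_states: int
    n_actions: int
    transitions: np.ndarray  # (S, A, S)
    rewards: np.ndarray      # (S, A)
    counts: np.ndarray       # (S, A, S)
    gamma: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma < 1.0:
            raise ConfigurationError(f"gamma must lie in [0, 1), got {self.gamma}")
        P = np.asarray(self.transitions, dtype=float)
        if P.shape != (self.n_states, self.n_actions, self.n_states):
            raise ValueError("transition tensor has wrong shape")
        if np.any(P < 0):
            raise ValueError("transition probabilities must be nonnegative")
        if not np.allclose(P.sum(axis=2), 1.0, atol=1e-12):
            raise ValueError("each (s, a) transition row must sum to 1")
        if not np.all(np.isfinite(self.rewards)):
            raise ValueError("rewards must be finite")

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_states": self.n_states,
                "n_actions": self.n_actions,
                "gamma": self.gamma,
                "transitions": self.transitions.tolist(),
                "rewards": self.rewards.tolist(),
                "counts": self.counts.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TabularMDP":
        d = json.loads(text)
        return cls(
            n_states=int(d["n_states"]),
            n_actions=int(d["n_actions"]),
            transitions=np.asarray(d["transitions"], dtype=float),
            rewards=np.asarray(d["rewards"], dtype=float),
            counts=np.asarray(d["counts"], dtype=float),
            gamma=float(d["gamma"]),
        )


def build_trajectories(
    states: pd.DataFrame, visits: pd.DataFrame, vocab: ActionVocabulary
) -> TrajectorySet:
    """Assemble per-patient trajectories from assigned states and raw visits.

    For consecutive visits (i, i+1) the step is (state_i, action_i,
    MMSE_{i+1} − MMSE_i): the reward is attributed to the action taken at the
    earlier visit, the one presumed to drive the observed change.  Visits
    whose state is unassigned (pruned tree leaf) break the trajectory; each
    maximal run of assigned visits with at least two members yields one
    trajectory segment.
    """
    required = {"patient_id", "visit_month", "state"}
    if not required.issubset(states.columns):
        raise SchemaError(f"state table must contain columns {sorted(required)}")
    merged = visits.merge(states, on=["patient_id", "visit_month"], how="inner")
    merged = merged.sort_values(["patient_id", "visit_month"], kind="mergesort")
    trajectories: list[Trajectory] = []
    for pid, grp in merged.groupby("patient_id", sort=True):
        st = grp["state"].to_numpy(dtype=object)
        mmse = grp["mmse"].to_numpy(dtype=float)
        acts = np.array([map_action(m, vocab) for m in grp["medication"]], dtype=np.int64)
        assigned = np.array([s is not None and not pd.isna(s) for s in st])
        # maximal runs of assigned visits
        i = 0
        n = len(grp)
        while i < n:
            if not assigned[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and assigned[j + 1]:
                j += 1
            if j > i:
                sl = slice(i, j)  # steps i..j-1
                trajectories.append(
                    Trajectory(
                        patient_id=str(pid),
                        states=np.array([int(s) for s in st[i:j]], dtype=np.int64),
                        actions=acts[sl],
                        rewards=mmse[i + 1 : j + 1] - mmse[i:j],
                        next_states=np.array([int(s) for s in st[i + 1 : j + 1]], dtype=np.int64),
                    )
                )
            i = j + 1
    return TrajectorySet(tuple(trajectories))


def estimate_mdp(
    trajs: TrajectorySet,
    n_states: int,
    n_actions: int = N_ACTIONS,
    gamma: float = 0.3,
    smoothing: float = 0.0,
) -> TabularMDP:
    """Count-based estimation of the tabular MDP from logged trajectories.

    P(s'|s,a) = (N(s,a,s') + smoothing) / (N(s,a,·) + smoothing·n_states) for
    observed (s,a); R(s,a) is the count-weighted mean step reward.  A state-
    action pair never observed gets a pessimistic self-loop whose reward is
    the worst step reward seen anywhere in the log, so that planners cannot
    exploit unobserved actions optimistically.
    """
    if not 0.0 <= gamma < 1.0:
        raise ConfigurationError(f"gamma must lie in [0, 1), got {gamma}")
    if smoothing < 0:
        raise ConfigurationError("smoothing must be nonnegative")
    if trajs.n_steps < 1:
        raise ValueError("at least one logged step is required")
    s, a, r, ns, _ = trajs.steps()
    N = np.zeros((n_states, n_actions, n_states), dtype=float)
    np.add.at(N, (s, a, ns), 1.0)
    r_sum = np.zeros((n_states, n_actions), dtype=float)
    np.add.at(r_sum, (s, a), r)
    n_sa = N.sum(axis=2)
    P = np.zeros_like(N)
    R = np.zeros_like(n_sa)
    worst = float(r.min())
    seen = n_sa > 0
    denom = n_sa + smoothing * n_states
    with np.errstate(invalid="ignore", divide="ignore"):
        P[seen] = (N[seen] + smoothing) / denom[seen, None]
        R[seen] = r_sum[seen] / n_sa[seen]
    for si, ai in zip(*np.where(~seen)):
        P[si, ai, si] = 1.0
        R[si, ai] = worst
    return TabularMDP(
        n_states=n_states,
        n_actions=n_actions,
        transitions=P,
        rewards=R,
        counts=N,
        gamma=gamma,
    )


def discounted_return(rewards: Sequence[float], gamma: float) -> float:
    """Discounted return G = Σ_k γ^k r_k of a finite reward sequence."""
    if not 0.0 <= gamma <= 1.0:
        raise ConfigurationError(f"gamma must lie in [0, 1], got {gamma}")
    r = np.asarray(list(rewards), dtype=float)
    if r.size == 0:
        return 0.0
    return float(r @ np.power(gamma, np.arange(r.size)))
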