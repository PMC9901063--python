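"""End-to-end experiment harness.

Runs the full pipeline — inclusion filtering, patient-level 60/20/20 split,
state-tree fitting on training visits, trajectory assembly, tabular MDP
estimation, policy learning (policy iteration and repeated Q-learning with
validation-based selection), baseline policies, and step-WIS evaluation with
bootstrap replication on held-out test trajectories — and orchestrates four
standard experiments on top of it:

* test 1 — training-set size sweep (fractions of the training patients);
* test 2 — comorbidity cohort comparison with per-state recommendations;
* test 3 — Q-learning learning-rate sweep;
* test 4 — state-count sweep via the leaf-pruning threshold.
"""

from __future__ import annotations

import hashlib
import json
import warnings
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .cohort_builder import (
    filter_patients,
    make_split,
    split_by_comorbidity,
    subsample_training,
)
from .errors import CoverageError, RegimenRLError
from .mdp_builder import ACTIONS, ActionVocabulary, N_ACTIONS, build_trajectories, estimate_mdp
from .ope import bootstrap_value, step_wis
from .solvers import (
    Policy,
    behavior_policy_empirical,
    clinician_policy,
    greedy_policy,
    policy_iteration,
    q_learning,
    random_policy,
    zero_policy,
)
from .state_model import assign_states, fit_state_tree, select_features


@dataclass(frozen=True)
class ExperimentConfig:
    """Knobs of the experiment harness, with the study's printed defaults."""

    cohort: str = "whole"
    data_fractions: tuple[float, ...] = (1.0, 0.8, 0.5, 0.3)
    alpha_sweep: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
    min_leaf_counts: tuple[int, ...] = (50, 100, 200)
    min_leaf_count: int = 50
    tree_max_depth: int = 4
    gamma: float = 0.3
    q_alpha: float = 0.05
    q_epochs: int = 50
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    n_train_repeats: int = 50
    n_boot: int = 100
    alpha_select: float = 0.05
    behavior_smoothing: float = 0.5
    mdp_smoothing: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("data_fractions", "alpha_sweep", "min_leaf_counts"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("data_fractions", "alpha_sweep", "min_leaf_counts", "split_fractions"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def derive_seed(master: int, *key: int | str) -> int:
    """A reproducible child seed below 2^31 from the master seed and a key path."""
    parts = [int(master)]
    for k in key:
        parts.append(zlib.crc32(k.encode()) if isinstance(k, str) else int(k))
    ss = np.random.SeedSequence(parts)
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass(frozen=True)
class ExperimentReport:
    """Per-condition policy-value summaries plus full provenance."""

    name: str
    results: tuple[dict, ...]
    recommendations: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "results": list(self.results),
                "recommendations": self.recommendations,
                "provenance": self.provenance,
            },
            indent=2,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.results))


def recommendation_table(policies: dict[str, Policy]) -> pd.DataFrame:
    """Per-state recommended action name per policy (one row per state)."""
    cols = {}
    for name, pol in policies.items():
        cols[name] = [ACTIONS[a] for a in pol.greedy_actions()]
    n_states = len(next(iter(cols.values())))
    return pd.DataFrame(cols, index=[f"S{s}" for s in range(n_states)])


def run_pipeline(
    visits: pd.DataFrame,
    config: ExperimentConfig,
    seed: int,
    train_fraction: float = 1.0,
    min_leaf_count: int | None = None,
    q_alpha: float | None = None,
) -> dict:
    """One complete learn-and-evaluate cycle on a visit table.

    The state tree, MDP, behavior policy and learned policies are fitted on
    training patients only; among ``n_train_repeats`` independently-seeded
    Q-learning runs, the greedy policy with the best validation step-WIS
    value is carried to testing; every policy is then evaluated on the
    held-out test trajectories by step-WIS with ``n_boot`` bootstrap
    replicates.  Fully deterministic given (visits, config, seed).
    """
    mlc = config.min_leaf_count if min_leaf_count is None else min_leaf_count
    qa = config.q_alpha if q_alpha is None else q_alpha
    vt = filter_patients(visits)
    split = make_split(vt, config.split_fractions, seed=derive_seed(seed, "split"))
    if train_fraction < 1.0:
        split = subsample_training(split, train_fraction, seed=derive_seed(seed, "subsample"))
    train_tbl = vt[vt["patient_id"].isin(split.train)].reset_index(drop=True)

    selection = select_features(train_tbl, config.alpha_select)
    model = fit_state_tree(
        train_tbl,
        selection,
        min_leaf_count=mlc,
        seed=derive_seed(seed, "tree"),
        max_depth=config.tree_max_depth,
    )
    states = assign_states(model, vt)
    vocab = ActionVocabulary.default()
    trajs = build_trajectories(states, vt, vocab)
    train_trajs = trajs.subset(split.train)
    val_trajs = trajs.subset(split.validation)
    test_trajs = trajs.subset(split.test)

    mdp = estimate_mdp(
        train_trajs, model.n_states, N_ACTIONS, gamma=config.gamma, smoothing=config.mdp_smoothing
    )
    behavior = behavior_policy_empirical(
        train_trajs, model.n_states, N_ACTIONS, smoothing=config.behavior_smoothing
    )
    pi_policy, _ = policy_iteration(mdp)

    best_q_policy, best_val = None, -np.inf
    for rep in range(config.n_train_repeats):
        qt = q_learning(
            train_trajs,
            model.n_states,
            N_ACTIONS,
            alpha=qa,
            gamma=config.gamma,
            epochs=config.q_epochs,
            seed=derive_seed(seed, "qlearn", rep),
        )
        candidate = greedy_policy(qt)
        try:
            val = step_wis(val_trajs, candidate, behavior, config.gamma).value
        except (CoverageError, ValueError):
            val = -np.inf
        if val > best_val or best_q_policy is None:
            best_q_policy, best_val = candidate, val

    policies = {
        "policy_iteration": pi_policy,
        "q_learning": best_q_policy,
        "clinician": clinician_policy(mdp, behavior),
        "behavior": behavior,
        "zero": zero_policy(model.n_states, N_ACTIONS),
        "random": random_policy(model.n_states, N_ACTIONS),
    }
    values: dict[str, dict] = {}
    for name, pol in policies.items():
        try:
            summary = bootstrap_value(
                test_trajs,
                pol,
                behavior,
                gamma=config.gamma,
                n_boot=config.n_boot,
                seed=derive_seed(seed, "boot", name),
            )
            values[name] = {
                "value": summary.point,
                "boot_mean": summary.mean,
                "boot_sd": summary.sd,
                "percentiles": summary.percentiles,
            }
        except (CoverageError, ValueError) as e:
            values[name] = {"value": None, "reason": str(e)}

    return {
        "values": values,
        "policies": policies,
        "model": model,
        "mdp": mdp,
        "split": split,
        "selection": selection,
        "n_test_trajectories": len(test_trajs),
        "provenance": {
            "seed": seed,
            "config_hash": config.hash(),
            "split_fractions": list(config.split_fractions),
            "split_sizes": [len(split.train), len(split.validation), len(split.test)],
            "train_fraction": train_fraction,
            "gamma": config.gamma,
            "q_alpha": qa,
            "q_epochs": config.q_epochs,
            "n_train_repeats": config.n_train_repeats,
            "n_boot": config.n_boot,
            "min_leaf_count": mlc,
            "n_states": model.n_states,
            "n_actions": N_ACTIONS,
            "actions": list(ACTIONS),
            "selected_features": list(selection.selected),
            "fit_on_train_only": True,
        },
    }


def _rows_from(run: dict, **condition) -> list[dict]:
    rows = []
    for policy, summary in run["values"].items():
        rows.append({**condition, "policy": policy, **summary})
    return rows


def run_test1(visits: pd.DataFrame, config: ExperimentConfig) -> ExperimentReport:
    """Training-set size sweep: learn and evaluate at each data fraction."""
    rows: list[dict] = []
    prov: dict = {"config": config.to_dict(), "runs": {}}
    for frac in config.data_fractions:
        seed = derive_seed(config.seed, "test1", int(round(frac * 100)))
        run = run_pipeline(visits, config, seed, train_fraction=frac)
        rows.extend(_rows_from(run, fraction=frac, n_states=run["provenance"]["n_states"]))
        prov["runs"][f"fraction_{frac}"] = run["provenance"]
    return ExperimentReport(name="test1", results=tuple(rows), provenance=prov)


def run_test2(visits: pd.DataFrame, config: ExperimentConfig) -> ExperimentReport:
    """Comorbidity cohort comparison with per-state recommendation tables."""
    rows: list[dict] = []
    recs: dict[str, dict] = {}
    prov: dict = {"config": config.to_dict(), "runs": {}}
    for name, cohort in split_by_comorbidity(visits).items():
        if cohort["patient_id"].nunique() < 3:
            warnings.warn(f"cohort {name!r} has too few patients; skipped", stacklevel=2)
            continue
        seed = derive_seed(config.seed, "test2", name)
        try:
            run = run_pipeline(cohort, config, seed)
        except RegimenRLError as e:
            warnings.warn(f"cohort {name!r} failed ({e}); skipped", stacklevel=2)
            continue
        rows.extend(_rows_from(run, cohort=name, n_states=run["provenance"]["n_states"]))
        recs[name] = recommendation_table(
            {
                k: run["policies"][k]
                for k in ("clinician", "q_learning", "policy_iteration")
            }
        ).to_dict()
        prov["runs"][name] = run["provenance"]
    return ExperimentReport(name="test2", results=tuple(rows), recommendations=recs, provenance=prov)


def run_test3(visits: pd.DataFrame, config: ExperimentConfig) -> ExperimentReport:
    """Q-learning learning-rate sweep over ``alpha_sweep``."""
    rows: list[dict] = []
    prov: dict = {"config": config.to_dict(), "runs": {}}
    for alpha in config.alpha_sweep:
        seed = derive_seed(config.seed, "test3", int(round(alpha * 100)))
        run = run_pipeline(visits, config, seed, q_alpha=alpha)
        rows.extend(_rows_from(run, alpha=alpha, n_states=run["provenance"]["n_states"]))
        prov["runs"][f"alpha_{alpha}"] = run["provenance"]
    return ExperimentReport(name="test3", results=tuple(rows), provenance=prov)


def run_test4(visits: pd.DataFrame, config: ExperimentConfig) -> ExperimentReport:
    """State-count sweep: refit at each leaf-pruning threshold."""
    rows: list[dict] = []
    prov: dict = {"config": config.to_dict(), "runs": {}}
    for mlc in config.min_leaf_counts:
        seed = derive_seed(config.seed, "test4", mlc)
        run = run_pipeline(visits, config, seed, min_leaf_count=mlc)
        rows.extend(
            _rows_from(run, min_leaf_count=mlc, n_states=run["provenance"]["n_states"])
        )
        prov["runs"][f"min_leaf_{mlc}"] = run["provenance"]
    return ExperimentReport(name="test4", results=tuple(rows), provenance=prov)
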