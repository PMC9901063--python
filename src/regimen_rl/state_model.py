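"""Discrete disease states from clinical assessments.

States are derived in two stages, mirroring routine EHR practice for coarse
disease staging: (1) ordinary least squares of MMSE on the candidate
assessments picks the statistically significant predictors; (2) a regression
tree fitted on those predictors partitions visits into leaves, each leaf
predicting an MMSE level.  Leaves with enough training visits become the
discrete states; rare leaves are ignored and the visits that land in them
are flagged unassigned.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.tree import DecisionTreeRegressor

from .errors import ModelDegenerateError, RoutingError

#: Candidate predictors of MMSE considered by the feature-selection OLS.
CANDIDATE_FEATURES: tuple[str, ...] = (
    "age", "adas13", "ravlt_immediate", "ravlt_learning", "cdrsb", "moca", "fdg",
)


@dataclass(frozen=True)
class FeatureSelection:
    """OLS-based selection of significant MMSE predictors."""

    candidates: tuple[str, ...]
    p_values: Mapping[str, float]
    selected: tuple[str, ...]
    alpha: float

    def __post_init__(self) -> None:
        if not set(self.selected) <= set(self.candidates):
            raise ValueError("selected features must be a subset of the candidates")


def select_features(t: pd.DataFrame, alpha_select: float = 0.05) -> FeatureSelection:
    """Regress MMSE on the candidate assessments; keep p < alpha_select.

    Collinear candidates (columns that do not increase the design-matrix
    rank) are dropped with a warning before fitting, so the OLS is always
    full rank.
    """
    if not 0.0 < alpha_select <= 1.0:
        raise ValueError("alpha_select must lie in (0, 1]")
    y = t["mmse"].to_numpy(dtype=float)
    kept: list[str] = []
    const = np.ones((len(t), 1))
    for c in CANDIDATE_FEATURES:
        trial = np.hstack([const] + [t[f].to_numpy(dtype=float)[:, None] for f in kept + [c]])
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            kept.append(c)
        else:
            warnings.warn(f"dropping collinear feature {c!r}", stacklevel=2)
    X = sm.add_constant(t[kept].to_numpy(dtype=float))
    fit = sm.OLS(y, X).fit()
    p_values = {f: float(fit.pvalues[i + 1]) for i, f in enumerate(kept)}
    selected = tuple(f for f in kept if p_values[f] < alpha_select)
    return FeatureSelection(
        candidates=CANDIDATE_FEATURES,
        p_values=p_values,
        selected=selected,
        alpha=alpha_select,
    )


@dataclass(frozen=True)
class StateModel:
    """A fitted regression tree with a leaf → state-id map.

    ``root`` is a nested node structure: internal nodes are
    ``{"feature", "threshold", "left", "right"}`` (values ≤ threshold route
    left, matching half-open (lo, hi] intervals); leaves are
    ``{"leaf_mmse", "state_id", "count"}`` with ``state_id`` None for pruned
    (ignored) leaves.  State ids are 0..n_states−1 in left-to-right leaf
    order.
    """

    root: dict
    features: tuple[str, ...]
    min_leaf_count: int
    n_states: int

    def route(self, row: Mapping[str, float]) -> tuple[int | None, float]:
        """Route one visit to its leaf; returns (state id or None, leaf MMSE)."""
        node = self.root
        while "feature" in node:
            x = row[node["feature"]]
            if pd.isna(x):
                raise RoutingError(f"missing feature {node['feature']!r} at predict time")
            node = node["left"] if x <= node["threshold"] else node["right"]
        return node["state_id"], node["leaf_mmse"]

    def leaves(self) -> list[dict]:
        out: list[dict] = []

        def walk(node: dict) -> None:
            if "feature" in node:
                walk(node["left"])
                walk(node["right"])
            else:
                out.append(node)

        walk(self.root)
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "root": self.root,
                "features": list(self.features),
                "min_leaf_count": self.min_leaf_count,
                "n_states": self.n_states,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "StateModel":
        d = json.loads(text)
        return cls(
            root=d["root"],
            features=tuple(d["features"]),
            min_leaf_count=int(d["min_leaf_count"]),
            n_states=int(d["n_states"]),
        )

    def rules(self) -> str:
        """Human-readable per-state interval rules, one line per leaf.

        Intervals are half-open ``(lo, hi]`` per feature; unconstrained
        features are omitted.  Pruned leaves are listed as ``ignored``.
        """
        lines: list[str] = []

        def fmt(lo: float, hi: float) -> str:
            lo_s = "" if lo == -np.inf else f"{lo:g}"
            hi_s = "" if hi == np.inf else f"{hi:g}"
            return f"({lo_s}, {hi_s}]"

        def walk(node: dict, bounds: dict[str, tuple[float, float]]) -> None:
            if "feature" in node:
                f, thr = node["feature"], node["threshold"]
                lo, hi = bounds.get(f, (-np.inf, np.inf))
                walk(node["left"], {**bounds, f: (lo, min(hi, thr))})
                walk(node["right"], {**bounds, f: (max(lo, thr), hi)})
            else:
                label = f"S{node['state_id']}" if node["state_id"] is not None else "ignored"
                parts = [f"{f} in {fmt(lo, hi)}" for f, (lo, hi) in sorted(bounds.items())]
                cond = ", ".join(parts) if parts else "(all visits)"
                lines.append(
                    f"{label}: {cond} -> predicted MMSE {node['leaf_mmse']:.1f} "
                    f"[{node['count']} visits]"
                )

        walk(self.root, {})
        return "\n".join(lines)


def _extract_tree(tree: DecisionTreeRegressor, features: tuple[str, ...]) -> dict:
    t = tree.tree_

    def build(i: int) -> dict:
        if t.children_left[i] == -1:
            return {
                "leaf_mmse": float(t.value[i].ravel()[0]),
                "state_id": None,
                "count": int(t.n_node_samples[i]),
            }
        return {
            "feature": features[t.feature[i]],
            "threshold": float(t.threshold[i]),
            "left": build(t.children_left[i]),
            "right": build(t.children_right[i]),
        }

    return build(0)


def fit_state_tree(
    t: pd.DataFrame,
    features: FeatureSelection,
    min_leaf_count: int = 50,
    seed: int = 0,
    max_depth: int = 4,
) -> StateModel:
    """Fit the state tree and grant state ids to sufficiently common leaves.

    The tree (squared-error criterion) is grown to at most ``max_depth``
    levels — coarse disease staging wants on the order of ten states, not a
    fully-grown CART — splitting only nodes with at least
    ``2·min_leaf_count`` visits and never below a leaf floor of
    ``min_leaf_count // 2``.  Leaves that end up with fewer than
    ``min_leaf_count`` visits are then ignored: they keep their region of
    feature space but receive no state id, so visits landing there are
    flagged unassigned downstream.  Deterministic for a fixed seed.
    """
    if min_leaf_count < 1:
        raise ValueError("min_leaf_count must be at least 1")
    if len(features.selected) == 0:
        raise ModelDegenerateError("no features selected; cannot fit a state tree")
    if len(t) < 2 * min_leaf_count:
        raise ModelDegenerateError(
            f"need at least {2 * min_leaf_count} visits to fit with "
            f"min_leaf_count={min_leaf_count}, got {len(t)}"
        )
    feats = tuple(features.selected)
    X = t[list(feats)].to_numpy(dtype=float)
    y = t["mmse"].to_numpy(dtype=float)
    tree = DecisionTreeRegressor(
        criterion="squared_error",
        max_depth=max_depth,
        min_samples_split=2 * min_leaf_count,
        min_samples_leaf=max(1, min_leaf_count // 2),
        random_state=seed,
    ).fit(X, y)
    root = _extract_tree(tree, feats)

    # grant ids to retained leaves in left-to-right order
    next_id = 0

    def grant(node: dict) -> None:
        nonlocal next_id
        if "feature" in node:
            grant(node["left"])
            grant(node["right"])
        elif node["count"] >= min_leaf_count:
            node["state_id"] = next_id
            next_id += 1

    grant(root)
    if next_id == 0:
        raise ModelDegenerateError(
            f"no leaf reached min_leaf_count={min_leaf_count}; state model is degenerate"
        )
    return StateModel(root=root, features=feats, min_leaf_count=min_leaf_count, n_states=next_id)


def assign_states(model: StateModel, t: pd.DataFrame) -> pd.DataFrame:
    """Route every visit down the tree; unassigned visits get a null state.

    Returns a (patient_id, visit_month, state) table aligned with ``t``;
    ``state`` is a nullable integer column.  A missing feature value raises a
    routing error naming the visit.
    """
    states: list[object] = []
    for _, row in t.iterrows():
        try:
            sid, _ = model.route(row)
        except RoutingError as e:
            raise RoutingError(
                f"{e} (patient {row['patient_id']}, month {row['visit_month']})"
            ) from None
        states.append(sid if sid is not None else pd.NA)
    return pd.DataFrame(
        {
            "patient_id": t["patient_id"].to_numpy(),
            "visit_month": t["visit_month"].to_numpy(),
            "state": pd.array(states, dtype="Int64"),
        }
    )
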