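"""Visit-table loading, inclusion criteria, repair, and cohort splitting.

The raw input is a longitudinal CSV, one row per clinic visit, with the
columns ``patient_id, visit_month, age, mmse, adas13, ravlt_immediate,
ravlt_learning, cdrsb, moca, fdg, medication, hypertension, depression``
(booleans as 0/1, missing values as empty fields).  Inclusion requires at
least two visits and, after forward-filling from earlier visits, complete
assessment data; patients are dropped whole, never visit-by-visit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SchemaError, SizingError

REQUIRED_COLUMNS: tuple[str, ...] = (
    "patient_id", "visit_month", "age", "mmse", "adas13",
    "ravlt_immediate", "ravlt_learning", "cdrsb", "moca", "fdg",
    "medication", "hypertension", "depression",
)

#: Columns subject to missingness and forward-fill repair.
ASSESSMENT_COLUMNS: tuple[str, ...] = (
    "mmse", "adas13", "ravlt_immediate", "ravlt_learning", "cdrsb", "moca", "fdg",
)

_NUMERIC_COLUMNS = ("visit_month", "age") + ASSESSMENT_COLUMNS


@dataclass(frozen=True)
class CohortSplit:
    """Patient-level train/validation/test partition."""

    train: frozenset[str]
    validation: frozenset[str]
    test: frozenset[str]

    def __post_init__(self) -> None:
        if (self.train & self.validation) or (self.train & self.test) or (
            self.validation & self.test
        ):
            raise ValueError("split parts must be disjoint")

    @property
    def all_patients(self) -> frozenset[str]:
        return self.train | self.validation | self.test


def load_visits(path) -> pd.DataFrame:
    """Read a visit CSV into a typed table sorted by (patient, month).

    Unparseable assessment cells become missing; hypertension/depression are
    coerced to booleans.  A missing required column raises a schema error
    naming it.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "medication": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = df.loc[:, list(REQUIRED_COLUMNS)].copy()
    for col in _NUMERIC_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["medication"] = df["medication"].fillna("").astype(str)
    for col in ("hypertension", "depression"):
        df[col] = pd.to_numeric(df[col], errors="coerce").fillna(0).astype(bool)
    df["visit_month"] = df["visit_month"].astype("Int64")
    df = df.sort_values(["patient_id", "visit_month"], kind="mergesort").reset_index(drop=True)
    return df


def save_visits(t: pd.DataFrame, path) -> None:
    """Write a visit table in the canonical CSV dialect (0/1 booleans, empty
    fields for missing values)."""
    out = t.loc[:, list(REQUIRED_COLUMNS)].copy()
    for col in ("hypertension", "depression"):
        out[col] = out[col].astype(int)
    out.to_csv(path, index=False)


def forward_fill(t: pd.DataFrame) -> pd.DataFrame:
    """Repair missing assessment values from the same patient's earlier visits.

    Each missing cell takes the most recent earlier non-missing value;
    leading missing values stay missing.  Non-missing cells are never
    altered.
    """
    out = t.sort_values(["patient_id", "visit_month"], kind="mergesort").reset_index(drop=True)
    cols = [c for c in ASSESSMENT_COLUMNS if c in out.columns]
    out[cols] = out.groupby("patient_id", sort=False)[cols].ffill()
    return out


def filter_patients(t: pd.DataFrame) -> pd.DataFrame:
    """Apply the inclusion criteria, returning the repaired retained table.

    Keeps patients with at least two visits whose assessment data is complete
    after forward-fill; whole patients are dropped when repair cannot restore
    completeness.  Idempotent.  An empty result is a warning, not a failure.
    """
    repaired = forward_fill(t)
    visit_counts = repaired.groupby("patient_id", sort=False)["visit_month"].size()
    complete = (
        repaired[list(ASSESSMENT_COLUMNS)]
        .notna()
        .all(axis=1)
        .groupby(repaired["patient_id"], sort=False)
        .all()
    )
    keep = visit_counts.index[(visit_counts >= 2) & complete.reindex(visit_counts.index)]
    out = repaired[repaired["patient_id"].isin(keep)].reset_index(drop=True)
    if out.empty:
        warnings.warn("inclusion criteria retained no patients (empty cohort)", stacklevel=2)
    return out


def split_by_comorbidity(t: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Five overlapping cohorts keyed by comorbidity flags.

    A patient with both flags belongs to both single-comorbidity cohorts and
    to the dual cohort; every patient belongs to ``whole``.
    """
    hyp = t["hypertension"].astype(bool)
    dep = t["depression"].astype(bool)
    return {
        "whole": t.copy(),
        "ad_only": t[~hyp & ~dep].reset_index(drop=True),
        "ad_hypertension": t[hyp].reset_index(drop=True),
        "ad_depression": t[dep].reset_index(drop=True),
        "ad_hypertension_depression": t[hyp & dep].reset_index(drop=True),
    }


def _largest_remainder(n: int, fractions: tuple[float, ...]) -> list[int]:
    exact = [f * n for f in fractions]
    sizes = [math.floor(e) for e in exact]
    short = n - sum(sizes)
    order = sorted(range(len(fractions)), key=lambda i: (-(exact[i] - sizes[i]), i))
    for i in order[:short]:
        sizes[i] += 1
    return sizes


def make_split(
    t: pd.DataFrame, fractions: tuple[float, float, float] = (0.6, 0.2, 0.2), seed: int = 0
) -> CohortSplit:
    """Random patient-level train/validation/test partition.

    Fractions must be positive and sum to one; sizes follow largest-remainder
    rounding so each part honors its fraction to within one patient.
    """
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ConfigurationError("fractions must be three positive numbers")
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ConfigurationError("fractions must sum to 1")
    ids = sorted(t["patient_id"].unique())
    if len(ids) < 3:
        raise SizingError(f"need at least 3 patients to split, got {len(ids)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    shuffled = [ids[i] for i in perm]
    n_train, n_val, n_test = _largest_remainder(len(ids), tuple(fractions))
    return CohortSplit(
        train=frozenset(shuffled[:n_train]),
        validation=frozenset(shuffled[n_train : n_train + n_val]),
        test=frozenset(shuffled[n_train + n_val :]),
    )


def subsample_training(split: CohortSplit, fraction: float, seed: int = 0) -> CohortSplit:
    """Reduce the training set to ⌈fraction·|train|⌉ patients.

    Validation and test sets are untouched; with fraction 1 the split is
    returned unchanged.
    """
    if not 0.0 < fraction <= 1.0:
        raise ConfigurationError(f"fraction must lie in (0, 1], got {fraction}")
    if fraction == 1.0:
        return split
    ids = sorted(split.train)
    k = math.ceil(fraction * len(ids))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(ids), size=k, replace=False)
    return CohortSplit(
        train=frozenset(ids[i] for i in chosen),
        validation=split.validation,
        test=split.test,
    )
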