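"""Tests of visit loading, inclusion criteria, repair, and splitting."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import regimen_rl as rr
from regimen_rl.cohort_builder import _largest_remainder
from regimen_rl.errors import ConfigurationError, SchemaError, SizingError

from conftest import tiny_visit_frame


class TestLoadVisits:
    def test_well_formed_rows_are_typed(self, tmp_path):
        t = tiny_visit_frame(
            [
                {"patient_id": "A", "visit_month": 0},
                {"patient_id": "A", "visit_month": 6},
                {"patient_id": "B", "visit_month": 0},
            ]
        )
        path = tmp_path / "v.csv"
        rr.save_visits(t, path)
        loaded = rr.load_visits(path)
        assert len(loaded) == 3
        assert loaded["mmse"].dtype == float
        assert loaded["hypertension"].dtype == bool

    def test_missing_required_column_names_it(self, tmp_path):
        t = tiny_visit_frame([{"patient_id": "A", "visit_month": 0}]).drop(columns=["mmse"])
        path = tmp_path / "v.csv"
        t.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="mmse"):
            rr.load_visits(path)

    def test_rows_sorted_by_patient_and_month(self, tmp_path):
        t = tiny_visit_frame(
            [
                {"patient_id": "A", "visit_month": 12},
                {"patient_id": "A", "visit_month": 0},
                {"patient_id": "A", "visit_month": 6},
            ]
        )
        path = tmp_path / "v.csv"
        rr.save_visits(t, path)
        loaded = rr.load_visits(path)
        assert list(loaded["visit_month"]) == [0, 6, 12]


class TestForwardFill:
    def test_missing_mmse_takes_previous_value(self):
        t = tiny_visit_frame(
            [
                {"patient_id": "A", "visit_month": 0, "mmse": 28.0},
                {"patient_id": "A", "visit_month": 6, "mmse": np.nan},
                {"patient_id": "A", "visit_month": 12, "mmse": 25.0},
            ]
        )
        assert list(rr.forward_fill(t)["mmse"]) == [28.0, 28.0, 25.0]

    def test_complete_table_unchanged(self):
        t = tiny_visit_frame(
            [{"patient_id": "A", "visit_month": m} for m in (0, 6, 12)]
        )
        pd.testing.assert_frame_equal(rr.forward_fill(t), t)

    def test_leading_missing_stays_missing(self):
        t = tiny_visit_frame(
            [
                {"patient_id": "A", "visit_month": 0, "mmse": np.nan},
                {"patient_id": "A", "visit_month": 6, "mmse": 27.0},
            ]
        )
        filled = rr.forward_fill(t)
        assert np.isnan(filled["mmse"].iloc[0]) and filled["mmse"].iloc[1] == 27.0
        # and the patient is then dropped by the inclusion filter
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert rr.filter_patients(t).empty

    def test_fill_never_crosses_patients(self):
        t = tiny_visit_frame(
            [
                {"patient_id": "A", "visit_month": 0, "mmse": 30.0},
                {"patient_id": "B", "visit_month": 0, "mmse": np.nan},
                {"patient_id": "B", "visit_month": 6, "mmse": 20.0},
            ]
        )
        assert np.isnan(rr.forward_fill(t)["mmse"].iloc[1])

    @given(st.lists(st.one_of(st.none(), st.floats(0, 30)), min_size=2, max_size=8))
    def test_nonmissing_cells_never_change(self, seq):
        t = tiny_visit_frame(
            [
                {"patient_id": "A", "visit_month": 6 * i, "mmse": np.nan if v is None else v}
                for i, v in enumerate(seq)
            ]
        )
        filled = rr.forward_fill(t)
        for i, v in enumerate(seq):
            if v is not None:
                assert filled["mmse"].iloc[i] == v


class TestFilterPatients:
    def test_single_visit_patient_removed(self):
        t = tiny_visit_frame(
            [
                {"patient_id": "A", "visit_month": 0},
                {"patient_id": "B", "visit_month": 0},
                {"patient_id": "B", "visit_month": 6},
            ]
        )
        out = rr.filter_patients(t)
        assert set(out["patient_id"]) == {"B"}

    def test_toy_table_retains_expected_patients(self):
        # A: fine.  B: one visit -> out.  C: leading missing mmse -> out.
        # D: repairable gap -> in.  E: fine.
        t = tiny_visit_frame(
            [
                {"patient_id": "A", "visit_month": 0},
                {"patient_id": "A", "visit_month": 6},
                {"patient_id": "B", "visit_month": 0},
                {"patient_id": "C", "visit_month": 0, "mmse": np.nan},
                {"patient_id": "C", "visit_month": 6},
                {"patient_id": "D", "visit_month": 0},
                {"patient_id": "D", "visit_month": 6, "mmse": np.nan},
                {"patient_id": "D", "visit_month": 12},
                {"patient_id": "E", "visit_month": 0},
                {"patient_id": "E", "visit_month": 6},
            ]
        )
        out = rr.filter_patients(t)
        assert set(out["patient_id"]) == {"A", "D", "E"}
        assert out["mmse"].notna().all()

    def test_idempotent(self, small_cohort):
        once = rr.filter_patients(small_cohort)
        twice = rr.filter_patients(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_empty_cohort_warns_not_fails(self):
        t = tiny_visit_frame([{"patient_id": "A", "visit_month": 0}])
        with pytest.warns(UserWarning, match="empty cohort"):
            out = rr.filter_patients(t)
        assert out.empty


class TestComorbidityCohorts:
    @pytest.fixture()
    def flagged(self):
        return tiny_visit_frame(
            [
                {"patient_id": "none", "visit_month": 0},
                {"patient_id": "hyp", "visit_month": 0, "hypertension": True},
                {"patient_id": "dep", "visit_month": 0, "depression": True},
                {"patient_id": "both", "visit_month": 0, "hypertension": True, "depression": True},
            ]
        )

    def test_membership_rules(self, flagged):
        cohorts = rr.split_by_comorbidity(flagged)
        ids = {k: set(v["patient_id"]) for k, v in cohorts.items()}
        assert ids["whole"] == {"none", "hyp", "dep", "both"}
        assert ids["ad_only"] == {"none"}
        assert ids["ad_hypertension"] == {"hyp", "both"}
        assert ids["ad_depression"] == {"dep", "both"}
        assert ids["ad_hypertension_depression"] == {"both"}

    def test_cohorts_overlap_by_design(self, flagged):
        cohorts = rr.split_by_comorbidity(flagged)
        total = sum(v["patient_id"].nunique() for k, v in cohorts.items() if k != "whole")
        assert total > cohorts["whole"]["patient_id"].nunique()


class TestSplits:
    @staticmethod
    def _cohort(n):
        return tiny_visit_frame(
            [
                {"patient_id": f"P{i:03d}", "visit_month": m}
                for i in range(n)
                for m in (0, 6)
            ]
        )

    def test_100_patients_split_60_20_20(self):
        split = rr.make_split(self._cohort(100), (0.6, 0.2, 0.2), seed=0)
        assert (len(split.train), len(split.validation), len(split.test)) == (60, 20, 20)

    def test_10_patients_split_6_2_2(self):
        split = rr.make_split(self._cohort(10), (0.6, 0.2, 0.2), seed=0)
        assert (len(split.train), len(split.validation), len(split.test)) == (6, 2, 2)

    def test_split_is_a_partition(self):
        t = self._cohort(37)
        split = rr.make_split(t, seed=3)
        parts = [split.train, split.validation, split.test]
        assert sum(len(p) for p in parts) == 37
        assert split.all_patients == set(t["patient_id"])

    def test_same_seed_same_split(self):
        t = self._cohort(50)
        assert rr.make_split(t, seed=9) == rr.make_split(t, seed=9)

    def test_too_few_patients_raises(self):
        with pytest.raises(SizingError):
            rr.make_split(self._cohort(2))

    @given(st.integers(3, 500))
    def test_largest_remainder_sums_to_n(self, n):
        assert sum(_largest_remainder(n, (0.6, 0.2, 0.2))) == n

    def test_subsample_identity_at_full_fraction(self):
        split = rr.make_split(self._cohort(20), seed=1)
        assert rr.subsample_training(split, 1.0, seed=5) == split

    @pytest.mark.parametrize("fraction,expected", [(0.5, 30), (0.3, 18), (0.8, 48)])
    def test_subsample_ceiling_rule(self, fraction, expected):
        split = rr.make_split(self._cohort(100), seed=2)
        sub = rr.subsample_training(split, fraction, seed=3)
        assert len(sub.train) == expected
        assert sub.validation == split.validation and sub.test == split.test
        assert sub.train <= split.train

    def test_subsample_invalid_fraction(self):
        split = rr.make_split(self._cohort(10), seed=0)
        with pytest.raises(ConfigurationError):
            rr.subsample_training(split, 0.0)
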