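"""EMR loading, filtering rules and the two clinical feature extractors."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from clindr import emr
from clindr.emr import (
    EMRDataset,
    change_profile,
    filter_cases_by_drug_count,
    max_signed_change,
    pre_treatment_values,
    read_emr,
    select_disease_tests,
    select_drug_tests,
)


def _write_tables(tmp_path, cases, rx, labs):
    paths = []
    for name, df in (("cases", cases), ("prescriptions", rx), ("labs", labs)):
        p = tmp_path / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths.append(p)
    return paths


class TestReadEmr:
    def test_identity_load(self, tmp_path):
        cases = pd.DataFrame(
            [("c1", "d1", 0, 5), ("c2", "d1", 0, 5), ("c3", "d2", 0, 5)],
            columns=["case_id", "diagnosis", "admission_day", "discharge_day"],
        )
        rx = pd.DataFrame(
            [("c1", "r1", 1, 3), ("c2", "r1", 1, 3), ("c3", "r2", 2, 4)],
            columns=["case_id", "drug", "start_day", "end_day"],
        )
        labs = pd.DataFrame(
            [("c1", "t1", 0, 1.0), ("c2", "t1", 0, 2.0), ("c3", "t1", 0, 3.0)],
            columns=["case_id", "test", "day", "value"],
        )
        ds = read_emr(*_write_tables(tmp_path, cases, rx, labs))
        assert len(ds.cases) == 3 and len(ds.prescriptions) == 3 and len(ds.labs) == 3
        assert sum(ds.drop_counts.values()) == 0

    def test_unresolvable_lab_row_dropped(self, tmp_path):
        cases = pd.DataFrame(
            [("c1", "d1", 0, 5)],
            columns=["case_id", "diagnosis", "admission_day", "discharge_day"],
        )
        rx = pd.DataFrame(columns=["case_id", "drug", "start_day", "end_day"])
        labs = pd.DataFrame(
            [("c1", "t1", 0, 1.0), ("ghost", "t1", 0, 2.0)],
            columns=["case_id", "test", "day", "value"],
        )
        ds = read_emr(*_write_tables(tmp_path, cases, rx, labs))
        assert len(ds.labs) == 1
        assert ds.drop_counts["labs"] == 1

    def test_empty_labs_is_not_an_error(self, tmp_path):
        cases = pd.DataFrame(
            [("c1", "d1", 0, 5)],
            columns=["case_id", "diagnosis", "admission_day", "discharge_day"],
        )
        rx = pd.DataFrame(columns=["case_id", "drug", "start_day", "end_day"])
        labs = pd.DataFrame(columns=["case_id", "test", "day", "value"])
        ds = read_emr(*_write_tables(tmp_path, cases, rx, labs))
        assert len(ds.labs) == 0

    def test_missing_column_is_fatal(self, tmp_path):
        cases = pd.DataFrame([("c1", "d1", 0, 5)],
                             columns=["case_id", "diagnosis", "admission_day", "discharge_day"])
        rx = pd.DataFrame(columns=["case_id", "drug", "start_day", "end_day"])
        labs = pd.DataFrame([("c1", 0, 1.0)], columns=["case_id", "day", "value"])
        with pytest.raises(ValueError, match="missing columns"):
            read_emr(*_write_tables(tmp_path, cases, rx, labs))


def _dataset_with_drug_counts(counts):
    cases, rx = [], []
    for i, n in enumerate(counts):
        cid = f"c{i}"
        cases.append((cid, "d", 0, 30))
        for j in range(n):
            rx.append((cid, f"r{j}", j, j + 1))
    return EMRDataset.from_frames(
        pd.DataFrame(cases, columns=["case_id", "diagnosis", "admission_day", "discharge_day"]),
        pd.DataFrame(rx, columns=["case_id", "drug", "start_day", "end_day"]),
        pd.DataFrame(columns=["case_id", "test", "day", "value"]),
    )


class TestDrugCountFilter:
    def test_case_above_threshold_removed_and_single_drug_kept(self):
        ds = _dataset_with_drug_counts([6, 1])
        out = filter_cases_by_drug_count(ds, max_drugs=5)
        assert list(out.cases["case_id"]) == ["c1"]

    def test_boundary_case_kept(self):
        ds = _dataset_with_drug_counts([5])
        assert len(filter_cases_by_drug_count(ds, max_drugs=5).cases) == 1

    def test_zero_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_cases_by_drug_count(_dataset_with_drug_counts([1]), max_drugs=0)

    def test_idempotent(self, small_cohort):
        once = filter_cases_by_drug_count(small_cohort.emr, 2)
        twice = filter_cases_by_drug_count(once, 2)
        pd.testing.assert_frame_equal(once.cases, twice.cases)
        pd.testing.assert_frame_equal(once.labs, twice.labs)


def _coverage_dataset(n_cases, covered):
    """``covered`` cases carry a pre-treatment result of t_hit; all carry t_all."""
    cases, labs = [], []
    for i in range(n_cases):
        cid = f"c{i}"
        cases.append((cid, "d", 0, 10))
        labs.append((cid, "t_all", 0, 1.0))
        if i < covered:
            labs.append((cid, "t_hit", 0, 1.0))
    return EMRDataset.from_frames(
        pd.DataFrame(cases, columns=["case_id", "diagnosis", "admission_day", "discharge_day"]),
        pd.DataFrame(columns=["case_id", "drug", "start_day", "end_day"]),
        pd.DataFrame(labs, columns=["case_id", "test", "day", "value"]),
    )


class TestDiseaseTestSelection:
    def test_half_coverage_selected_at_forty_percent(self):
        assert "t_hit" in select_disease_tests(_coverage_dataset(10, 5), 0.40)

    def test_thirty_percent_coverage_excluded(self):
        assert "t_hit" not in select_disease_tests(_coverage_dataset(10, 3), 0.40)

    def test_zero_threshold_rejected(self):
        with pytest.raises(ValueError):
            select_disease_tests(_coverage_dataset(4, 2), 0.0)

    def test_post_treatment_results_do_not_count(self):
        # the only result of t_hit sits after the first drug start
        cases = pd.DataFrame([("c0", "d", 0, 10)],
                             columns=["case_id", "diagnosis", "admission_day", "discharge_day"])
        rx = pd.DataFrame([("c0", "r", 2, 6)], columns=["case_id", "drug", "start_day", "end_day"])
        labs = pd.DataFrame([("c0", "t_hit", 5, 1.0)], columns=["case_id", "test", "day", "value"])
        ds = EMRDataset.from_frames(cases, rx, labs)
        assert select_disease_tests(ds, 0.4) == set()


def _episode_dataset(n_episodes, results_per_episode=2):
    cases, rx, labs = [], [], []
    for i in range(n_episodes):
        cid = f"c{i}"
        cases.append((cid, "d", 0, 10))
        rx.append((cid, f"r{i % 3}", 2, 6))
        for j in range(results_per_episode):
            labs.append((cid, "t", 2 + j, float(j)))
    return EMRDataset.from_frames(
        pd.DataFrame(cases, columns=["case_id", "diagnosis", "admission_day", "discharge_day"]),
        pd.DataFrame(rx, columns=["case_id", "drug", "start_day", "end_day"]),
        pd.DataFrame(labs, columns=["case_id", "test", "day", "value"]),
    )


class TestDrugTestSelection:
    def test_meeting_both_criteria_selected(self):
        ds = _episode_dataset(12)
        assert select_drug_tests(ds, min_drug_coverage=0.3, min_cases=10) == {"t"}

    def test_too_few_observed_episodes_excluded(self):
        ds = _episode_dataset(1)
        assert select_drug_tests(ds, min_drug_coverage=0.3, min_cases=1000) == set()

    def test_single_result_episodes_do_not_qualify(self):
        ds = _episode_dataset(12, results_per_episode=1)
        assert select_drug_tests(ds, min_drug_coverage=0.3, min_cases=1) == set()

    def test_thresholds_honored_verbatim(self):
        ds = _episode_dataset(11)
        assert select_drug_tests(ds, min_cases=10) == {"t"}
        assert select_drug_tests(ds, min_cases=11) == set()


class TestPreTreatmentValues:
    def test_results_after_first_drug_start_excluded(self, toy_emr):
        # c1 starts drugA on day 3: days 1 and 3 count, day 5 does not
        vals = pre_treatment_values(toy_emr, "dX", "t1")
        assert set(vals) == {100.0, 110.0, 50.0}

    def test_case_without_prescriptions_contributes_everything(self, toy_emr):
        assert set(pre_treatment_values(toy_emr, "dY", "t1")) == {70.0, 75.0}

    def test_unknown_disease_gives_empty(self, toy_emr):
        assert pre_treatment_values(toy_emr, "nope", "t1").size == 0

    def test_never_later_than_first_start(self, small_cohort):
        ds = small_cohort.emr
        first = ds.first_drug_start()
        pre = ds.pre_treatment_labs()
        merged = pre.join(first.rename("start"), on="case_id")
        with_rx = merged.dropna(subset=["start"])
        assert (with_rx["day"] <= with_rx["start"]).all()


def _change_oracle(values):
    """Exhaustive search over ordered pairs; returns max |diff| and the achievers."""
    best = max(abs(values[j] - values[i]) for i, j in combinations(range(len(values)), 2))
    signed = {values[j] - values[i] for i, j in combinations(range(len(values)), 2)
              if abs(values[j] - values[i]) == best}
    return best, signed


class TestChangeProfile:
    def test_signed_maximum_change(self, toy_emr):
        # drugA window [3, 8] on c1 captures days 3 and 5: 110 -> 95
        assert change_profile(toy_emr, "drugA", "t1").tolist() == [-15.0]

    def test_constant_series_gives_zero(self):
        assert max_signed_change([100.0, 100.0]) == 0.0

    def test_single_result_episode_skipped(self, toy_emr):
        # drugB window [2, 6] on c2 only contains day 4
        assert change_profile(toy_emr, "drugB", "t1").size == 0

    def test_spec_example_prefers_larger_fall(self):
        assert max_signed_change([100.0, 110.0, 95.0]) == -15.0

    @given(st.lists(st.integers(min_value=-50, max_value=50), min_size=2, max_size=8))
    def test_matches_exhaustive_pair_search(self, values):
        values = [float(v) for v in values]
        f = max_signed_change(values)
        best, signed = _change_oracle(values)
        assert abs(f) == best
        assert f in signed
        if best in signed and -best in signed and best > 0:
            # sign tie between an equal rise and fall resolves to the rise
            assert f == best

    def test_bulk_table_agrees_with_single_profile(self, small_cohort):
        table = emr.change_table(small_cohort.emr)
        drug = table["drug"].iloc[0]
        test = table["test"].iloc[0]
        direct = change_profile(small_cohort.emr, drug, test)
        via_table = table.loc[(table["drug"] == drug) & (table["test"] == test), "F"]
        assert sorted(direct.tolist()) == sorted(via_table.tolist())
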