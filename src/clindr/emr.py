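"""EMR event tables and the cohort filtering rules feeding the clinical similarities.

The clinical evidence base is an inpatient-style record: each hospitalization
*case* carries exactly one diagnosis code, a set of drug prescription episodes
with start/end days, and timestamped laboratory results.  Time is an integer
day grid, 0-based relative to admission; every window is inclusive on both
ends.

Two derived quantities drive everything downstream:

* the *pre-treatment* lab values of a case — results dated no later than the
  case's earliest prescription start (results on the start day itself count,
  since most diagnoses precede the first order on the same day); cases with
  no prescriptions contribute all of their results.  These characterize the
  disease.
* the *drug-change* value ``F`` of an episode — the signed difference over
  the time-ordered pair of in-window results with the largest absolute
  difference.  These characterize the drug.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CASE_COLUMNS = ("case_id", "diagnosis", "admission_day", "discharge_day")
PRESCRIPTION_COLUMNS = ("case_id", "drug", "start_day", "end_day")
LAB_COLUMNS = ("case_id", "test", "day", "value")


@dataclass(frozen=True)
class Case:
    """One admission–discharge event with a single diagnosis code."""

    case_id: str
    diagnosis: str
    admission_day: int
    discharge_day: int

    def __post_init__(self) -> None:
        if not self.diagnosis:
            raise ValueError("diagnosis must be non-empty")
        if self.admission_day > self.discharge_day:
            raise ValueError("admission_day must be <= discharge_day")


@dataclass(frozen=True)
class PrescriptionEpisode:
    case_id: str
    drug: str
    start_day: int
    end_day: int

    def __post_init__(self) -> None:
        if self.start_day > self.end_day:
            raise ValueError("start_day must be <= end_day")


@dataclass(frozen=True)
class LabResult:
    case_id: str
    test: str
    day: int
    value: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError("lab value must be finite")


@dataclass
class EMRDataset:
    """Cases, prescription episodes and lab results as validated DataFrames.

    Row-level invariants (referential integrity, ordered day intervals,
    finite values, days within the stay) are enforced at construction;
    offending rows are dropped and counted in ``drop_counts``.
    """

    cases: pd.DataFrame
    prescriptions: pd.DataFrame
    labs: pd.DataFrame
    drop_counts: dict = field(default_factory=dict)

    @classmethod
    def from_frames(
        cls,
        cases: pd.DataFrame,
        prescriptions: pd.DataFrame,
        labs: pd.DataFrame,
    ) -> "EMRDataset":
        for frame, cols, name in (
            (cases, CASE_COLUMNS, "cases"),
            (prescriptions, PRESCRIPTION_COLUMNS, "prescriptions"),
            (labs, LAB_COLUMNS, "labs"),
        ):
            missing = set(cols) - set(frame.columns)
            if missing:
                raise ValueError(f"{name} table is missing columns {sorted(missing)}")

        drops: dict[str, int] = {}

        cases = cases.loc[:, list(CASE_COLUMNS)].copy()
        cases["case_id"] = cases["case_id"].astype(str)
        cases["diagnosis"] = cases["diagnosis"].astype(str)
        ok = (
            (cases["diagnosis"].str.len() > 0)
            & (cases["admission_day"] <= cases["discharge_day"])
            & ~cases["case_id"].duplicated()
        )
        drops["cases"] = int((~ok).sum())
        cases = cases.loc[ok].reset_index(drop=True)
        stay = cases.set_index("case_id")[["admission_day", "discharge_day"]]

        prescriptions = prescriptions.loc[:, list(PRESCRIPTION_COLUMNS)].copy()
        prescriptions["case_id"] = prescriptions["case_id"].astype(str)
        prescriptions["drug"] = prescriptions["drug"].astype(str)
        joined = prescriptions.join(stay, on="case_id")
        ok = (
            joined["admission_day"].notna()
            & (prescriptions["start_day"] <= prescriptions["end_day"])
            & (prescriptions["start_day"] >= joined["admission_day"])
            & (prescriptions["start_day"] <= joined["discharge_day"])
        )
        drops["prescriptions"] = int((~ok).sum())
        prescriptions = prescriptions.loc[ok].reset_index(drop=True)

        labs = labs.loc[:, list(LAB_COLUMNS)].copy()
        labs["case_id"] = labs["case_id"].astype(str)
        labs["test"] = labs["test"].astype(str)
        labs["value"] = pd.to_numeric(labs["value"], errors="coerce")
        joined = labs.join(stay, on="case_id")
        ok = (
            joined["admission_day"].notna()
            & np.isfinite(labs["value"].to_numpy(dtype=float, na_value=np.nan))
            & (labs["day"] >= joined["admission_day"])
            & (labs["day"] <= joined["discharge_day"])
        )
        drops["labs"] = int((~ok).sum())
        labs = labs.loc[ok].reset_index(drop=True)

        total_dropped = sum(drops.values())
        if total_dropped:
            logger.info("dropped %d invalid rows: %s", total_dropped, drops)
        return cls(cases=cases, prescriptions=prescriptions, labs=labs, drop_counts=drops)

    # -- derived views -----------------------------------------------------

    def first_drug_start(self) -> pd.Series:
        """Earliest prescription start per case (index: case_id).

        Cases with no prescriptions are absent from the result.
        """
        if self.prescriptions.empty:
            return pd.Series(dtype=float, name="start_day")
        return self.prescriptions.groupby("case_id")["start_day"].min()

    def pre_treatment_labs(self) -> pd.DataFrame:
        """Lab rows dated no later than the case's first drug start, with diagnosis.

        Cases without prescriptions contribute all their results.
        """
        first = self.first_drug_start()
        labs = self.labs.join(first.rename("first_start"), on="case_id")
        keep = labs["first_start"].isna() | (labs["day"] <= labs["first_start"])
        out = labs.loc[keep, list(LAB_COLUMNS)]
        diag = self.cases.set_index("case_id")["diagnosis"]
        return out.join(diag, on="case_id")

    def in_window_labs(self) -> pd.DataFrame:
        """Lab rows joined to every prescription episode whose window contains them.

        Adds ``drug`` and a per-row ``episode`` id; a lab result appearing in
        the windows of two episodes is attached to both.
        """
        rx = self.prescriptions.reset_index(names="episode")
        merged = self.labs.merge(rx, on="case_id")
        keep = (merged["day"] >= merged["start_day"]) & (merged["day"] <= merged["end_day"])
        return merged.loc[keep, ["case_id", "drug", "episode", "test", "day", "value"]]


def read_emr(cases_path, prescriptions_path, labs_path) -> EMRDataset:
    """Load and validate the three tab-separated event tables.

    Missing files or missing required columns are fatal; rows violating the
    dataset invariants are dropped and counted in ``EMRDataset.drop_counts``.
    """
    cases = pd.read_csv(cases_path, sep="\t")
    prescriptions = pd.read_csv(prescriptions_path, sep="\t")
    labs = pd.read_csv(labs_path, sep="\t")
    return EMRDataset.from_frames(cases, prescriptions, labs)


def write_emr(ds: EMRDataset, cases_path, prescriptions_path, labs_path) -> None:
    ds.cases.to_csv(cases_path, sep="\t", index=False)
    ds.prescriptions.to_csv(prescriptions_path, sep="\t", index=False)
    ds.labs.to_csv(labs_path, sep="\t", index=False, float_format="%.12g")


def filter_cases_by_drug_count(ds: EMRDataset, max_drugs: int = 5) -> EMRDataset:
    """Keep cases with at most ``max_drugs`` distinct prescribed drugs.

    Polypharmacy blurs the attribution of a lab change to any single drug, so
    heavily co-medicated cases are excluded before drug–drug similarity is
    computed.  Cases with no prescriptions are retained.
    """
    if max_drugs < 1:
        raise ValueError("max_drugs must be >= 1")
    counts = ds.prescriptions.groupby("case_id")["drug"].nunique()
    bad = set(counts.index[counts > max_drugs])
    if not bad:
        return EMRDataset(ds.cases, ds.prescriptions, ds.labs, dict(ds.drop_counts))
    keep_cases = ~ds.cases["case_id"].isin(bad)
    return EMRDataset(
        cases=ds.cases.loc[keep_cases].reset_index(drop=True),
        prescriptions=ds.prescriptions.loc[~ds.prescriptions["case_id"].isin(bad)].reset_index(drop=True),
        labs=ds.labs.loc[~ds.labs["case_id"].isin(bad)].reset_index(drop=True),
        drop_counts=dict(ds.drop_counts),
    )


def select_disease_tests(ds: EMRDataset, min_coverage: float = 0.40) -> set[str]:
    """Tests with a pre-treatment result in at least ``min_coverage`` of cases."""
    if not 0 < min_coverage <= 1:
        raise ValueError("min_coverage must be in (0, 1]")
    n_cases = len(ds.cases)
    if n_cases == 0:
        return set()
    pre = ds.pre_treatment_labs()
    covered = pre.groupby("test")["case_id"].nunique()
    return set(covered.index[covered / n_cases >= min_coverage])


def select_drug_tests(
    ds: EMRDataset, min_drug_coverage: float = 0.30, min_cases: int = 1000
) -> set[str]:
    """Tests usable for drug–drug similarity.

    A prescription episode *qualifies* for a test when at least two results of
    that test fall inside the episode window (a change needs two time points).
    A test is selected when (a) the fraction of drugs with at least one
    qualifying episode reaches ``min_drug_coverage`` and (b) the number of
    qualifying episodes exceeds ``min_cases``.
    """
    if min_drug_coverage <= 0 or min_cases <= 0:
        raise ValueError("thresholds must be positive")
    n_drugs = ds.prescriptions["drug"].nunique()
    if n_drugs == 0:
        return set()
    win = ds.in_window_labs()
    if win.empty:
        return set()
    per_ep = win.groupby(["test", "episode", "drug"]).size().rename("n").reset_index()
    qual = per_ep.loc[per_ep["n"] >= 2]
    episodes = qual.groupby("test")["episode"].nunique()
    drugs = qual.groupby("test")["drug"].nunique()
    selected = set()
    for test in episodes.index:
        if drugs[test] / n_drugs >= min_drug_coverage and episodes[test] > min_cases:
            selected.add(test)
    return selected


def pre_treatment_values(ds: EMRDataset, disease: str, test: str) -> np.ndarray:
    """All pre-treatment results of ``test`` over cases diagnosed with ``disease``."""
    pre = ds.pre_treatment_labs()
    sel = pre.loc[(pre["diagnosis"] == disease) & (pre["test"] == test), "value"]
    return sel.to_numpy(dtype=float)


def max_signed_change(values: Iterable[float]) -> float:
    """Signed difference over the time-ordered pair with maximal absolute difference.

    ``values`` must already be in time order.  When a rise and a fall tie in
    magnitude the rise (positive sign) is reported; requires >= 2 values.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    rise = float(np.max(v - np.minimum.accumulate(v)))
    fall = float(np.max(np.maximum.accumulate(v) - v))
    return rise if rise >= fall else -fall


def change_table(ds: EMRDataset) -> pd.DataFrame:
    """One drug-change value F per (drug, test, episode) with >= 2 in-window results.

    Columns: drug, test, episode, F.
    """
    win = ds.in_window_labs()
    if win.empty:
        return pd.DataFrame(columns=["drug", "test", "episode", "F"])
    win = win.sort_values(["drug", "test", "episode", "day"], kind="stable").reset_index(drop=True)
    g = win.groupby(["drug", "test", "episode"], sort=True)
    v = win["value"]
    rise = (v - g["value"].cummin()).groupby(
        [win["drug"], win["test"], win["episode"]], sort=True
    ).max()
    fall = (g["value"].cummax() - v).groupby(
        [win["drug"], win["test"], win["episode"]], sort=True
    ).max()
    size = g.size()
    out = pd.DataFrame({"rise": rise, "fall": fall, "n": size}).reset_index()
    out = out.loc[out["n"] >= 2]
    out["F"] = np.where(out["rise"] >= out["fall"], out["rise"], -out["fall"])
    return out[["drug", "test", "episode", "F"]].reset_index(drop=True)


def change_profile(ds: EMRDataset, drug: str, test: str) -> np.ndarray:
    """The F values of ``drug`` on ``test`` across its qualifying episodes."""
    table = change_table(ds)
    sel = table.loc[(table["drug"] == drug) & (table["test"] == test), "F"]
    return sel.to_numpy(dtype=float)
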