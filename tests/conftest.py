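import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from clindr import pipeline, simulate
from clindr.emr import EMRDataset

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_cohort():
    """The default planted cohort: 4 matched classes, 50 cases/disease, seed 17."""
    return simulate.generate(simulate.CohortConfig())


@pytest.fixture(scope="session")
def default_result(default_cohort):
    """Full pipeline (similarities, predictions, 10-fold CV) on the default cohort."""
    return pipeline.run_pipeline(default_cohort, n_perm=1000)


SMALL_CONFIG = dict(
    diseases_per_class=3,
    drugs_per_class=3,
    cases_per_disease=15,
    n_tests=4,
    tests_per_case=4,
)
SMALL_PARAMS = pipeline.FilterParams(min_cases=10)


@pytest.fixture(scope="session")
def small_cohort():
    """A scaled-down planted cohort for cheap structural checks."""
    return simulate.generate(simulate.CohortConfig(seed=5, **SMALL_CONFIG))


@pytest.fixture(scope="session")
def small_result(small_cohort):
    return pipeline.run_pipeline(small_cohort, params=SMALL_PARAMS, n_perm=100, k=5)


@pytest.fixture()
def toy_emr():
    """Three cases, two drugs, labs spanning pre- and in-treatment windows."""
    cases = pd.DataFrame(
        [
            ("c1", "dX", 0, 10),
            ("c2", "dX", 0, 10),
            ("c3", "dY", 0, 10),
        ],
        columns=["case_id", "diagnosis", "admission_day", "discharge_day"],
    )
    rx = pd.DataFrame(
        [
            ("c1", "drugA", 3, 8),
            ("c2", "drugB", 2, 6),
        ],
        columns=["case_id", "drug", "start_day", "end_day"],
    )
    labs = pd.DataFrame(
        [
            ("c1", "t1", 1, 100.0),
            ("c1", "t1", 3, 110.0),
            ("c1", "t1", 5, 95.0),
            ("c2", "t1", 0, 50.0),
            ("c2", "t1", 4, 60.0),
            ("c3", "t1", 2, 70.0),
            ("c3", "t1", 9, 75.0),
        ],
        columns=["case_id", "test", "day", "value"],
    )
    return EMRDataset.from_frames(cases, rx, labs)


@pytest.fixture(scope="session")
def toy_dag():
    """8-gene two-branch term DAG used as the semantic-similarity ground truth.

    root -> {A, B, bg}; A -> {A1, A2}; B -> {B1}.  After propagation A1
    covers 2 of the 8 annotated genes, so IC(A1) = ln 4.
    """
    dag = nx.DiGraph()
    dag.add_edges_from(
        [("A", "root"), ("B", "root"), ("bg", "root"),
         ("A1", "A"), ("A2", "A"), ("B1", "B")]
    )
    annotations = {
        "g1": frozenset({"A1"}),
        "g2": frozenset({"A1", "A2"}),
        "g3": frozenset({"A2"}),
        "g4": frozenset({"A"}),
        "g5": frozenset({"B1"}),
        "g6": frozenset({"B1"}),
        "g7": frozenset({"B"}),
        "g8": frozenset({"bg"}),
    }
    return dag, annotations
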