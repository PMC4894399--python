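"""Drug–drug and disease–disease similarity from laboratory-test distributions.

For a disease pair, the two pre-treatment value distributions of a laboratory
test are compared with a two-sided Wilcoxon rank-sum test; for a drug pair,
the distributions of per-episode signed maximum changes F are compared the
same way.  A *large* p-value — failure to distinguish the two distributions —
is read as similarity.  Per test, the p-values over all pairs are rank
normalized to [0, 1]; the final matrix takes, per pair, the maximum rank
value across tests, remembering which test contributed it.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .emr import EMRDataset, change_table
from .matrices import (
    LARGER_IS_SIMILAR,
    SimilarityMatrix,
    SimilarityResult,
    aggregate_max,
    rank_normalize,
)

#: Smallest usable sample per distribution; below it a comparison is marked
#: unavailable (similarity 0) rather than producing an unstable p-value.
DEFAULT_MIN_GROUP = 5

#: Largest combined sample for which the exact null distribution of the
#: rank-sum statistic is enumerated (ties force the normal approximation).
EXACT_MAX_N = 12


def rank_sum_pvalue(
    a: Sequence[float], b: Sequence[float], min_group: int = DEFAULT_MIN_GROUP
) -> Optional[float]:
    """Two-sided Wilcoxon rank-sum p-value, or None when a group is too small.

    Uses exact enumeration of the rank-sum null when the combined sample has
    at most 12 untied observations, and the tie-corrected normal
    approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < min_group or b.size < min_group:
        return None
    combined = np.concatenate([a, b])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (combined.size <= EXACT_MAX_N and no_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def _pairwise_pvalues(
    groups: dict[str, np.ndarray], entities: Sequence[str], min_group: int
) -> dict[tuple[str, str], Optional[float]]:
    empty = np.empty(0)
    return {
        (a, b): rank_sum_pvalue(groups.get(a, empty), groups.get(b, empty), min_group)
        for a, b in combinations(entities, 2)
    }


def _build_result(
    entities: Sequence[str],
    per_test_values: dict[str, dict[str, np.ndarray]],
    min_group: int,
) -> SimilarityResult:
    per_measure_sims: dict[str, dict] = {}
    tables: dict[str, pd.DataFrame] = {}
    for test in sorted(per_test_values):
        pvals = _pairwise_pvalues(per_test_values[test], entities, min_group)
        sims = rank_normalize(pvals, LARGER_IS_SIMILAR)
        per_measure_sims[test] = sims
        tables[test] = pd.DataFrame(
            [
                (a, b, np.nan if pvals[(a, b)] is None else pvals[(a, b)], sims[(a, b)])
                for a, b in combinations(entities, 2)
            ],
            columns=["entity_a", "entity_b", "p_value", "similarity"],
        )
    aggregated = aggregate_max(entities, per_measure_sims)
    return SimilarityResult(per_measure=tables, aggregated=aggregated)


def disease_similarity(
    ds: EMRDataset, tests: Iterable[str], min_group: int = DEFAULT_MIN_GROUP
) -> SimilarityResult:
    """Disease–disease similarity from pre-treatment lab value distributions."""
    tests = sorted(set(tests))
    diseases = sorted(ds.cases["diagnosis"].unique())
    pre = ds.pre_treatment_labs()
    pre = pre.loc[pre["test"].isin(tests)]
    grouped = pre.groupby(["test", "diagnosis"])["value"]
    per_test: dict[str, dict[str, np.ndarray]] = {t: {} for t in tests}
    for (test, disease), vals in grouped:
        per_test[test][disease] = vals.to_numpy(dtype=float)
    return _build_result(diseases, per_test, min_group)


def drug_similarity(
    ds: EMRDataset, tests: Iterable[str], min_group: int = DEFAULT_MIN_GROUP
) -> SimilarityResult:
    """Drug–drug similarity from per-episode signed maximum-change distributions."""
    tests = sorted(set(tests))
    drugs = sorted(ds.prescriptions["drug"].unique())
    changes = change_table(ds)
    changes = changes.loc[changes["test"].isin(tests)]
    per_test: dict[str, dict[str, np.ndarray]] = {t: {} for t in tests}
    for (test, drug), vals in changes.groupby(["test", "drug"])["F"]:
        per_test[test][drug] = vals.to_numpy(dtype=float)
    return _build_result(drugs, per_test, min_group)
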