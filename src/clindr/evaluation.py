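"""Cross-validation, the guilt-by-association baseline, enrichment tests and
similarity-matrix clustering.

Cross-validation splits the known indications into k seeded folds.  Per
fold, the held-out indications are removed from the network *before* degrees
and weights are computed (no leakage through w), scores are recomputed on
the reduced network, and the AUC measures how well the held-out true edges
rank above all never-indicated pairs (exhaustive negatives, so the result is
deterministic given the fold split).  Model variants score with the fused f,
with P_c alone (clinical-only) or with P_g alone (genomic-only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom
from sklearn.metrics import roc_auc_score

from .matrices import SimilarityMatrix
from .scoring import DEFAULT_THETA, IndicationNetwork, final_score, score_matrix

VARIANTS = ("full", "clinical", "genomic")


@dataclass
class VariantResult:
    fold_aucs: list[float]
    pooled_auc: float
    sensitivity: float
    specificity: float


@dataclass
class CVResult:
    """Fold assignment plus per-variant fold/pooled AUC and theta operating point.

    The pooled AUC is the fold-size-weighted mean of fold AUCs (weights:
    held-out positives per fold), which keeps it inside [min, max] of the
    fold values.
    """

    fold_of: dict[tuple[str, str], int]
    k: int
    seed: int
    variants: dict[str, VariantResult] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in sorted(self.variants):
            v = self.variants[name]
            for i, auc in enumerate(v.fold_aucs):
                rows.append((name, i, auc, np.nan, np.nan))
            rows.append((name, -1, v.pooled_auc, v.sensitivity, v.specificity))
        return pd.DataFrame(
            rows, columns=["variant", "fold", "auc", "sensitivity", "specificity"]
        )


def assign_folds(
    positives: Iterable[tuple[str, str]], k: int, seed: int
) -> dict[tuple[str, str], int]:
    """Seeded partition of the positive edges into k folds."""
    edges = sorted(positives)
    if k > len(edges):
        raise ValueError(f"k={k} exceeds the {len(edges)} positive edges")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(edges))
    fold_of = {}
    for fold, chunk in enumerate(np.array_split(order, k)):
        for idx in chunk:
            fold_of[edges[idx]] = fold
    return fold_of


def cross_validate(
    network: IndicationNetwork,
    clinical_drugs: SimilarityMatrix,
    clinical_diseases: SimilarityMatrix,
    genomic_drugs: SimilarityMatrix,
    genomic_diseases: SimilarityMatrix,
    k: int = 10,
    seed: int = 0,
    variants: Sequence[str] = VARIANTS,
    theta: float = DEFAULT_THETA,
) -> CVResult:
    """k-fold edge-holdout evaluation of the full / clinical / genomic models."""
    for v in variants:
        if v not in VARIANTS:
            raise ValueError(f"unknown variant {v!r}")
    fold_of = assign_folds(network.positives, k, seed)
    drugs, diseases = network.drugs, network.diseases
    drug_idx = {d: i for i, d in enumerate(drugs)}
    disease_idx = {t: j for j, t in enumerate(diseases)}
    neg_mask = np.ones((len(drugs), len(diseases)), dtype=bool)
    for d, t in network.positives:
        neg_mask[drug_idx[d], disease_idx[t]] = False

    per_variant: dict[str, dict[str, list]] = {
        v: {"auc": [], "n_pos": [], "sens": [], "spec": []} for v in variants
    }
    for fold in range(k):
        held = [e for e, f in fold_of.items() if f == fold]
        if not held:
            continue
        train = network.without(held)
        Pc, _ = score_matrix(train, clinical_drugs, clinical_diseases)
        Pg, _ = score_matrix(train, genomic_drugs, genomic_diseases)
        scores = {"clinical": Pc, "genomic": Pg, "full": final_score(Pc, Pg)}
        pos_cells = ([drug_idx[d] for d, _ in held], [disease_idx[t] for _, t in held])
        for v in variants:
            s = scores[v]
            pos_scores = s[pos_cells]
            neg_scores = s[neg_mask]
            y = np.concatenate([np.ones(pos_scores.size), np.zeros(neg_scores.size)])
            auc = float(roc_auc_score(y, np.concatenate([pos_scores, neg_scores])))
            per_variant[v]["auc"].append(auc)
            per_variant[v]["n_pos"].append(len(held))
            per_variant[v]["sens"].append(float(np.mean(pos_scores > theta)))
            per_variant[v]["spec"].append(float(np.mean(neg_scores <= theta)))

    result = CVResult(fold_of=fold_of, k=k, seed=seed)
    for v in variants:
        aucs = per_variant[v]["auc"]
        w = np.asarray(per_variant[v]["n_pos"], dtype=float)
        result.variants[v] = VariantResult(
            fold_aucs=aucs,
            pooled_auc=float(np.average(aucs, weights=w)),
            sensitivity=float(np.average(per_variant[v]["sens"], weights=w)),
            specificity=float(np.mean(per_variant[v]["spec"])),
        )
    return result


def gba_predict(network: IndicationNetwork) -> frozenset[tuple[str, str]]:
    """Guilt-by-association baseline: deterministic, unscored predictions.

    For every disease pair sharing at least one indicated drug, each drug
    indicated for exactly one of the two diseases is predicted for the other.
    """
    drugs_of: dict[str, set[str]] = {}
    for d, t in network.positives:
        drugs_of.setdefault(t, set()).add(d)
    predictions: set[tuple[str, str]] = set()
    for t1, t2 in combinations(sorted(drugs_of), 2):
        a, b = drugs_of[t1], drugs_of[t2]
        if a & b:
            for d in a - b:
                predictions.add((d, t2))
            for d in b - a:
                predictions.add((d, t1))
    return frozenset(predictions)


def hypergeom_enrichment(
    hits_in_selection: int,
    selection_size: int,
    hits_in_universe: int,
    universe_size: int,
) -> float:
    """Upper-tail hypergeometric probability of >= the observed hit count."""
    k, n, K, N = hits_in_selection, selection_size, hits_in_universe, universe_size
    if min(k, n, K, N) < 0 or n > N or K > N or k > min(n, K) or k < max(0, n + K - N):
        raise ValueError("inconsistent counts for the hypergeometric test")
    return float(hypergeom.sf(k - 1, N, K, n))


@dataclass
class ClusterResult:
    ids: tuple[str, ...]
    linkage: np.ndarray
    labels: np.ndarray  # flat cluster id per entity, aligned with ids


def cluster_matrix(
    sim: SimilarityMatrix,
    linkage_method: str = "average",
    height: Optional[float] = None,
    n_clusters: Optional[int] = None,
) -> ClusterResult:
    """Agglomerative clustering of entities on distance 1 - similarity.

    Entities are ordered lexicographically before linkage so equal-distance
    merges resolve deterministically.  Flat clusters come from a distance cut
    (``height``, default 0.5) or from ``n_clusters``.
    """
    if len(sim.ids) < 2:
        raise ValueError("need at least two entities to cluster")
    order = np.argsort(np.asarray(sim.ids, dtype=object))
    ids = tuple(sim.ids[i] for i in order)
    values = sim.values[np.ix_(order, order)]
    dist = 1.0 - values
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage_method)
    if n_clusters is not None:
        labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    else:
        labels = hierarchy.fcluster(Z, t=0.5 if height is None else height, criterion="distance")
    return ClusterResult(ids=ids, linkage=Z, labels=labels)
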