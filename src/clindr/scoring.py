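"""Degree-weighted similarity transfer over the known-indication network.

The model assumption is that similar drugs treat similar diseases.  A
candidate pair (drug s_i, disease t_j) inherits support from every known
indication (s_p, t_q): the transferred score is w(s_p) * Sim_S(s_i, s_p) *
Sim_T(t_j, t_q), maximized over all known indications.  w(s_p) =
ln(1 + D(s_p)) / ln(1 + D_max) up-weights drugs that already carry many
indications (a proxy for repositioning activity) while staying in (0, 1].
Run with the clinical matrices this yields P_c, with the genomic matrices
P_g, and the two are fused into the final edge value

    f = P_c + 0.8 * P_g * cos((pi/2) * (P_c - P_g))

which ranges over [0, 1.8], is driven primarily by P_c, and grants the full
genomic bonus only when the two channels agree.  A pair is called a
repositioning candidate when f exceeds the decision threshold theta
(default 0.9).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .matrices import SimilarityMatrix

DEFAULT_THETA = 0.9
GENOMIC_BONUS = 0.8  # fixes the attainable maximum of f at 1.8


@dataclass(frozen=True)
class IndicationNetwork:
    """Bipartite drug–disease graph; ``positives`` are the known indications."""

    drugs: tuple[str, ...]
    diseases: tuple[str, ...]
    positives: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "drugs", tuple(sorted(map(str, self.drugs))))
        object.__setattr__(self, "diseases", tuple(sorted(map(str, self.diseases))))
        object.__setattr__(
            self, "positives", frozenset((str(a), str(b)) for a, b in self.positives)
        )
        drug_set, disease_set = set(self.drugs), set(self.diseases)
        for d, t in self.positives:
            if d not in drug_set or t not in disease_set:
                raise ValueError(f"edge ({d}, {t}) references an unknown node")

    def degree(self, drug: str) -> int:
        return sum(1 for d, _ in self.positives if d == drug)

    def degrees(self) -> dict[str, int]:
        deg = {d: 0 for d in self.drugs}
        for d, _ in self.positives:
            deg[d] += 1
        return deg

    def without(self, edges: Iterable[tuple[str, str]]) -> "IndicationNetwork":
        removed = {(str(a), str(b)) for a, b in edges}
        return IndicationNetwork(self.drugs, self.diseases, self.positives - removed)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        drugs: Optional[Sequence[str]] = None,
        diseases: Optional[Sequence[str]] = None,
    ) -> "IndicationNetwork":
        edges = [(str(a), str(b)) for a, b in edges]
        drugs = tuple(drugs) if drugs is not None else tuple({a for a, _ in edges})
        diseases = tuple(diseases) if diseases is not None else tuple({b for _, b in edges})
        return cls(drugs, diseases, frozenset(edges))

    def to_tsv(self, path) -> None:
        pd.DataFrame(sorted(self.positives), columns=["drug", "disease"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(
        cls, path, drugs: Optional[Sequence[str]] = None, diseases: Optional[Sequence[str]] = None
    ) -> "IndicationNetwork":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls.from_edges(zip(df["drug"], df["disease"]), drugs, diseases)


def node_weight(network: IndicationNetwork, drug: str) -> float:
    """Logarithmic saturating indication-degree weight in [0, 1]."""
    d_max = max(network.degrees().values(), default=0)
    if d_max == 0:
        raise ValueError("network has no known indications")
    return math.log1p(network.degree(drug)) / math.log1p(d_max)


def edge_score(
    network: IndicationNetwork,
    sim_drugs: SimilarityMatrix,
    sim_diseases: SimilarityMatrix,
    drug: str,
    disease: str,
    exclude_self: bool = True,
) -> float:
    """Maximum degree-weighted similarity transfer from the known indications.

    ``exclude_self`` drops the candidate edge itself from the max (relevant
    only when scoring a pair that is already a known indication); entities
    absent from a similarity matrix contribute similarity 0.
    """
    score, _ = edge_score_detail(network, sim_drugs, sim_diseases, drug, disease, exclude_self)
    return score


def edge_score_detail(
    network: IndicationNetwork,
    sim_drugs: SimilarityMatrix,
    sim_diseases: SimilarityMatrix,
    drug: str,
    disease: str,
    exclude_self: bool = True,
) -> tuple[float, Optional[tuple[str, str]]]:
    """Edge score plus the supporting known indication achieving the max."""
    degrees = network.degrees()
    d_max = max(degrees.values(), default=0)
    if d_max == 0:
        return 0.0, None
    log_dmax = math.log1p(d_max)
    best, support = 0.0, None
    for p, q in sorted(network.positives):
        if exclude_self and (p, q) == (drug, disease):
            continue
        w = math.log1p(degrees[p]) / log_dmax
        s = w * sim_drugs.get(drug, p) * sim_diseases.get(disease, q)
        if s > best:
            best, support = s, (p, q)
    return best, support


def score_matrix(
    network: IndicationNetwork,
    sim_drugs: SimilarityMatrix,
    sim_diseases: SimilarityMatrix,
) -> tuple[np.ndarray, np.ndarray]:
    """Transfer scores for every (drug, disease) cell of the network node grid.

    Returns ``(P, support)`` where ``P[i, j]`` is the max-transfer score for
    (drugs[i], diseases[j]) and ``support[i, j]`` indexes the winning known
    indication in ``sorted(network.positives)`` (-1 where no transfer
    applies).  Known-indication cells exclude themselves from their own max.
    """
    drugs, diseases = network.drugs, network.diseases
    m, n = len(drugs), len(diseases)
    positives = sorted(network.positives)
    P = np.zeros((m, n))
    support = np.full((m, n), -1, dtype=int)
    if not positives:
        return P, support
    degrees = network.degrees()
    d_max = max(degrees.values())
    log_dmax = math.log1p(d_max)
    drug_idx = {d: i for i, d in enumerate(drugs)}
    disease_idx = {t: j for j, t in enumerate(diseases)}
    for k, (p, q) in enumerate(positives):
        w = math.log1p(degrees[p]) / log_dmax
        col_s = np.array([sim_drugs.get(d, p) for d in drugs])
        col_t = np.array([sim_diseases.get(t, q) for t in diseases])
        contrib = np.outer(w * col_s, col_t)
        better = contrib > P
        P[better] = contrib[better]
        support[better] = k
    # a known indication must not support itself
    for p, q in positives:
        i, j = drug_idx[p], disease_idx[q]
        s, sup = edge_score_detail(network, sim_drugs, sim_diseases, p, q, exclude_self=True)
        P[i, j] = s
        support[i, j] = positives.index(sup) if sup is not None else -1
    return P, support


def final_score(p_c, p_g):
    """Integrated edge value f = P_c + 0.8 * P_g * cos((pi/2)(P_c - P_g)).

    Accepts scalars or arrays in [0, 1]; the result lies in [0, 1.8], is
    strictly increasing in P_c, and attains 1.8 exactly at P_c = P_g = 1.
    """
    p_c = np.asarray(p_c, dtype=float)
    p_g = np.asarray(p_g, dtype=float)
    if np.any(p_c < 0) or np.any(p_c > 1) or np.any(p_g < 0) or np.any(p_g > 1):
        raise ValueError("P_c and P_g must lie in [0, 1]")
    f = p_c + GENOMIC_BONUS * p_g * np.cos((np.pi / 2.0) * (p_c - p_g))
    return float(f) if f.ndim == 0 else f


@dataclass(frozen=True)
class EdgeScore:
    drug: str
    disease: str
    p_c: float
    p_g: float
    f: float
    predicted_label: int
    support_c: Optional[tuple[str, str]]
    support_g: Optional[tuple[str, str]]


def score_edge(
    network: IndicationNetwork,
    clinical_drugs: SimilarityMatrix,
    clinical_diseases: SimilarityMatrix,
    genomic_drugs: SimilarityMatrix,
    genomic_diseases: SimilarityMatrix,
    drug: str,
    disease: str,
    theta: float = DEFAULT_THETA,
) -> EdgeScore:
    """Full scoring of a single candidate pair, with both supporting edges."""
    p_c, sup_c = edge_score_detail(network, clinical_drugs, clinical_diseases, drug, disease)
    p_g, sup_g = edge_score_detail(network, genomic_drugs, genomic_diseases, drug, disease)
    f = final_score(p_c, p_g)
    return EdgeScore(
        drug=drug, disease=disease, p_c=p_c, p_g=p_g, f=f,
        predicted_label=int(f > theta), support_c=sup_c, support_g=sup_g,
    )


def predict(
    network: IndicationNetwork,
    clinical_drugs: SimilarityMatrix,
    clinical_diseases: SimilarityMatrix,
    genomic_drugs: SimilarityMatrix,
    genomic_diseases: SimilarityMatrix,
    theta: float = DEFAULT_THETA,
) -> pd.DataFrame:
    """Score every non-indicated (drug, disease) pair and rank by f.

    Output columns: drug, disease, p_c, p_g, f, predicted (1 iff f > theta),
    support_drug, support_disease — the known indication backing the clinical
    transfer P_c, which dominates f.  Rows sort by f descending with a
    lexicographic (drug, disease) tie-break, so the table is deterministic.
    """
    positives = sorted(network.positives)
    Pc, sup_c = score_matrix(network, clinical_drugs, clinical_diseases)
    Pg, _ = score_matrix(network, genomic_drugs, genomic_diseases)
    f = final_score(Pc, Pg)
    rows = []
    pos_set = network.positives
    for i, drug in enumerate(network.drugs):
        for j, disease in enumerate(network.diseases):
            if (drug, disease) in pos_set:
                continue
            sc = positives[sup_c[i, j]] if sup_c[i, j] >= 0 else ("", "")
            rows.append(
                (drug, disease, Pc[i, j], Pg[i, j], f[i, j], int(f[i, j] > theta), sc[0], sc[1])
            )
    out = pd.DataFrame(
        rows,
        columns=["drug", "disease", "p_c", "p_g", "f", "predicted", "support_drug", "support_disease"],
    )
    out = out.sort_values(
        ["f", "drug", "disease"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)
    return out
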