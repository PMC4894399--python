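"""Similarity containers and rank normalization shared by the clinical and genomic sides.

Raw pairwise scores (Wilcoxon p-values, permutation p-values, semantic
similarity scores) live on incomparable scales across laboratory tests and
measures.  Rank normalization maps each batch of raw scores onto [0, 1] by
tie-averaged rank — the most similar pair gets exactly 1 — so that matrices
from heterogeneous sources can be aggregated by a cell-wise maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

Pair = tuple[Hashable, Hashable]

LARGER_IS_SIMILAR = "larger_is_similar"
SMALLER_IS_SIMILAR = "smaller_is_similar"


def rank_normalize(
    scores: Mapping[Pair, Optional[float]], direction: str
) -> dict[Pair, float]:
    """Map raw pairwise scores to similarities in (0, 1] by tie-averaged rank.

    ``direction`` states which end of the raw scale means "more similar":
    ``larger_is_similar`` (e.g. Wilcoxon p-values, where failure to
    distinguish two distributions is evidence of similarity; semantic
    similarity scores) or ``smaller_is_similar`` (e.g. permutation p-values
    of network overlap, where significance means similarity).  Similarity is
    (average rank in the most-similar-ranks-highest orientation) / (number of
    scored pairs); pairs with no score (``None``/NaN) map to 0.
    """
    if direction not in (LARGER_IS_SIMILAR, SMALLER_IS_SIMILAR):
        raise ValueError(f"unknown direction {direction!r}")
    pairs = list(scores)
    raw = np.array(
        [np.nan if scores[p] is None else float(scores[p]) for p in pairs], dtype=float
    )
    avail = np.isfinite(raw)
    out = {p: 0.0 for p in pairs}
    n = int(avail.sum())
    if n == 0:
        return out
    oriented = raw[avail] if direction == LARGER_IS_SIMILAR else -raw[avail]
    ranks = rankdata(oriented, method="average")
    sims = ranks / n
    for k, i in enumerate(np.flatnonzero(avail)):
        out[pairs[i]] = float(sims[k])
    return out


@dataclass
class SimilarityMatrix:
    """Symmetric entity x entity similarity in [0, 1]; diagonal 1; missing pairs 0.

    ``source`` optionally records, per cell, the label of the measure (e.g.
    the laboratory test) whose rank value won the max-aggregation.
    """

    ids: tuple[str, ...]
    values: np.ndarray
    source: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.ids = tuple(str(i) for i in self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("values must be square and match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0):
            raise ValueError("diagonal must be 1")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("similarities must lie in [0, 1]")
        self._index = {e: i for i, e in enumerate(self.ids)}

    def get(self, a: str, b: str) -> float:
        """Similarity of (a, b); entities absent from the matrix score 0."""
        ia = self._index.get(a)
        ib = self._index.get(b)
        if ia is None or ib is None:
            return 0.0
        return float(self.values[ia, ib])

    def column(self, entity: str) -> np.ndarray:
        """Similarity of every row entity to ``entity`` (zeros if unknown)."""
        i = self._index.get(entity)
        if i is None:
            return np.zeros(len(self.ids))
        return self.values[:, i].copy()

    def best_source(self, a: str, b: str) -> Optional[str]:
        if self.source is None:
            return None
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return None
        tag = self.source[ia, ib]
        return None if tag is None else str(tag)

    @classmethod
    def from_pair_dict(
        cls,
        ids: Sequence[str],
        sims: Mapping[Pair, float],
        sources: Optional[Mapping[Pair, str]] = None,
    ) -> "SimilarityMatrix":
        ids = tuple(str(i) for i in ids)
        index = {e: i for i, e in enumerate(ids)}
        n = len(ids)
        values = np.zeros((n, n))
        np.fill_diagonal(values, 1.0)
        src = np.full((n, n), None, dtype=object) if sources is not None else None
        for (a, b), s in sims.items():
            i, j = index[str(a)], index[str(b)]
            values[i, j] = values[j, i] = s
            if src is not None:
                tag = sources.get((a, b))
                src[i, j] = src[j, i] = tag
        return cls(ids=ids, values=values, source=src)

    def to_pairs_frame(self) -> pd.DataFrame:
        """Long form: one row per unordered off-diagonal pair (zeros included)."""
        rows = []
        for i, a in enumerate(self.ids):
            for j in range(i + 1, len(self.ids)):
                b = self.ids[j]
                tag = self.source[i, j] if self.source is not None else None
                rows.append((a, b, self.values[i, j], "" if tag is None else tag))
        return pd.DataFrame(rows, columns=["entity_a", "entity_b", "similarity", "best_test"])

    def to_tsv(self, path) -> None:
        self.to_pairs_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")

    @classmethod
    def from_tsv(cls, path) -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"entity_a": str, "entity_b": str})
        ids = sorted(set(df["entity_a"]) | set(df["entity_b"]))
        sims = {(r.entity_a, r.entity_b): r.similarity for r in df.itertuples()}
        sources = None
        if "best_test" in df.columns:
            sources = {
                (r.entity_a, r.entity_b): r.best_test
                for r in df.itertuples()
                if isinstance(r.best_test, str) and r.best_test
            }
        return cls.from_pair_dict(ids, sims, sources)


@dataclass
class SimilarityResult:
    """Per-measure pair tables plus the max-aggregated similarity matrix."""

    per_measure: dict[str, pd.DataFrame] = field(default_factory=dict)
    aggregated: SimilarityMatrix = None  # type: ignore[assignment]

    def write(self, directory, prefix: str) -> None:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for measure in sorted(self.per_measure):
            safe = str(measure).replace("/", "_").replace(":", "_")
            self.per_measure[measure].to_csv(
                directory / f"{prefix}_{safe}.tsv", sep="\t", index=False, float_format="%.12g"
            )
        self.aggregated.to_tsv(directory / f"{prefix}_aggregated.tsv")


def aggregate_max(
    ids: Sequence[str],
    per_measure_sims: Mapping[str, Mapping[Pair, float]],
) -> SimilarityMatrix:
    """Cell-wise maximum across measures, recording the winning measure per cell.

    Ties go to the lexicographically smallest measure label; pairs unavailable
    in every measure stay 0 with no source tag.
    """
    best: dict[Pair, float] = {}
    tags: dict[Pair, str] = {}
    for measure in sorted(per_measure_sims, key=str):
        for pair, s in per_measure_sims[measure].items():
            if s > best.get(pair, 0.0):
                best[pair] = s
                tags[pair] = str(measure)
    return SimilarityMatrix.from_pair_dict(ids, best, tags)
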