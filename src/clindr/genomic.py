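"""Genomic similarities: PPI-module overlap with a permutation null, and
Resnik term-based semantic similarity between seed-gene sets.

Each drug or disease carries a set of seed genes.  Its interaction module is
the seeds plus their first neighbors in the protein–protein interaction
graph.  Module similarity is the overlap coefficient |A∩B| / min(|A|,|B|),
and its significance is an empirical p-value against modules rebuilt from
size-matched random seed sets.  Semantic similarity between two gene sets is
the symmetrized best-match average of pairwise gene similarities, where a
gene pair scores the information content of the most informative common
ancestor of their annotation terms (Resnik).  Both raw measures are rank
normalized — permutation p with smaller-is-similar, Resnik with
larger-is-similar — and aggregated per pair by maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import FrozenSet, Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .matrices import (
    LARGER_IS_SIMILAR,
    SMALLER_IS_SIMILAR,
    SimilarityResult,
    aggregate_max,
)

OVERLAP_COEFFICIENT = "overlap"
JACCARD = "jaccard"


@dataclass
class GenomicsBundle:
    """PPI graph, per-entity seed-gene sets, term DAG and gene annotations.

    ``dag`` is directed child -> parent with a unique root reachable from
    every term.  The gene universe for permutation draws is the union of PPI
    nodes and all seed genes.
    """

    ppi: nx.Graph
    seed_sets: dict[str, FrozenSet[str]]
    dag: nx.DiGraph
    annotations: dict[str, FrozenSet[str]]

    def __post_init__(self) -> None:
        self.ppi = nx.Graph(self.ppi)
        self.ppi.remove_edges_from(nx.selfloop_edges(self.ppi))
        self.seed_sets = {str(k): frozenset(map(str, v)) for k, v in self.seed_sets.items()}
        self.annotations = {str(k): frozenset(map(str, v)) for k, v in self.annotations.items()}
        if not nx.is_directed_acyclic_graph(self.dag):
            raise ValueError("term graph must be acyclic")
        roots = [t for t in self.dag.nodes if self.dag.out_degree(t) == 0]
        if len(roots) != 1:
            raise ValueError(f"term DAG must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        self.gene_universe: tuple[str, ...] = tuple(
            sorted(set(map(str, self.ppi.nodes)) | set().union(*self.seed_sets.values(), set()))
        )
        self._gene_index = {g: i for i, g in enumerate(self.gene_universe)}
        self._adjacency: Optional[np.ndarray] = None

    def adjacency(self) -> np.ndarray:
        """Boolean adjacency over the gene universe (built lazily, cached)."""
        if self._adjacency is None:
            n = len(self.gene_universe)
            adj = np.zeros((n, n), dtype=bool)
            for a, b in self.ppi.edges:
                i, j = self._gene_index[str(a)], self._gene_index[str(b)]
                adj[i, j] = adj[j, i] = True
            self._adjacency = adj
        return self._adjacency

    def gene_indices(self, genes: Iterable[str]) -> np.ndarray:
        return np.array(sorted(self._gene_index[g] for g in genes), dtype=int)


def module_network(bundle: GenomicsBundle, entity: str) -> frozenset[str]:
    """Seed genes of ``entity`` plus their first PPI neighbors (empty if no seeds)."""
    seeds = bundle.seed_sets.get(entity, frozenset())
    module = set(seeds)
    for g in seeds:
        if bundle.ppi.has_node(g):
            module.update(map(str, bundle.ppi.neighbors(g)))
    return frozenset(module)


def overlap_score(a: frozenset, b: frozenset, method: str = OVERLAP_COEFFICIENT) -> float:
    """Normalized overlap of two gene sets; 0 when either set is empty."""
    if not a or not b:
        return 0.0
    inter = len(a & b)
    if method == OVERLAP_COEFFICIENT:
        return inter / min(len(a), len(b))
    if method == JACCARD:
        return inter / len(a | b)
    raise ValueError(f"unknown overlap method {method!r}")


def _module_mask(adj: np.ndarray, seed_idx: np.ndarray, n: int) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    mask[seed_idx] = True
    mask |= adj[seed_idx].any(axis=0)
    return mask


def overlap_pvalue(
    bundle: GenomicsBundle,
    entity_a: str,
    entity_b: str,
    n_perm: int = 1000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    method: str = OVERLAP_COEFFICIENT,
) -> Optional[float]:
    """Empirical p-value of the observed module overlap under size-matched
    random seed sets.

    Each permutation redraws both seed sets (same sizes) uniformly without
    replacement from the gene universe, rebuilds first-neighbor modules, and
    recomputes the overlap.  Add-one smoothing keeps p strictly positive:
    p = (1 + #{permuted >= observed}) / (n_perm + 1).  Returns None when
    either entity has no seed genes.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    seeds_a = bundle.seed_sets.get(entity_a, frozenset())
    seeds_b = bundle.seed_sets.get(entity_b, frozenset())
    if not seeds_a or not seeds_b:
        return None
    observed = overlap_score(
        module_network(bundle, entity_a), module_network(bundle, entity_b), method
    )
    if rng is None:
        rng = np.random.default_rng(seed)
    adj = bundle.adjacency()
    n = len(bundle.gene_universe)
    na, nb = len(seeds_a), len(seeds_b)
    count = 0
    for _ in range(n_perm):
        ia = rng.choice(n, size=na, replace=False)
        ib = rng.choice(n, size=nb, replace=False)
        ma = _module_mask(adj, ia, n)
        mb = _module_mask(adj, ib, n)
        inter = int(np.count_nonzero(ma & mb))
        if method == OVERLAP_COEFFICIENT:
            denom = min(int(ma.sum()), int(mb.sum()))
            perm = inter / denom if denom else 0.0
        else:
            union = int(np.count_nonzero(ma | mb))
            perm = inter / union if union else 0.0
        if perm >= observed:
            count += 1
    return (1 + count) / (n_perm + 1)


@dataclass
class TermIC:
    """Per-term information content (nats) with the ancestor closure cached."""

    ic: dict[str, float]
    ancestors: dict[str, frozenset[str]]
    n_annotated: int

    def term_similarity(self, t1: str, t2: str) -> float:
        """IC of the most informative common ancestor (0 if only the root is shared)."""
        common = self.ancestors.get(t1, frozenset()) & self.ancestors.get(t2, frozenset())
        if not common:
            return 0.0
        return max(self.ic.get(t, 0.0) for t in common)


def _ancestor_closure(dag: nx.DiGraph) -> dict[str, frozenset[str]]:
    # edges run child -> parent, so graph-descendants are semantic ancestors
    return {t: frozenset(nx.descendants(dag, t)) | {t} for t in dag.nodes}


def resnik_ic(dag: nx.DiGraph, annotations: Mapping[str, Iterable[str]]) -> TermIC:
    """Information content after true-path propagation of gene annotations.

    A gene annotated to a term is counted at that term and every ancestor up
    to the root; IC(t) = -ln(genes at-or-below t / genes annotated at root).
    Terms absent from the DAG are ignored; a corpus with no usable
    annotation is an error.
    """
    ancestors = _ancestor_closure(dag)
    counts: dict[str, int] = {}
    total = 0
    for gene in sorted(annotations):
        terms = [t for t in annotations[gene] if t in ancestors]
        if not terms:
            continue
        total += 1
        propagated: set[str] = set()
        for t in terms:
            propagated |= ancestors[t]
        for t in propagated:
            counts[t] = counts.get(t, 0) + 1
    if total == 0:
        raise ValueError("no gene annotates any term in the DAG")
    ic = {t: -math.log(c / total) for t, c in counts.items()}
    return TermIC(ic=ic, ancestors=ancestors, n_annotated=total)


def gene_similarity(
    ic: TermIC, g1: str, g2: str, annotations: Mapping[str, Iterable[str]]
) -> float:
    """Max over annotation term pairs of the MICA information content."""
    t1s = [t for t in annotations.get(g1, ()) if t in ic.ancestors]
    t2s = [t for t in annotations.get(g2, ()) if t in ic.ancestors]
    if not t1s or not t2s:
        return 0.0
    return max(ic.term_similarity(a, b) for a in t1s for b in t2s)


def resnik_set_similarity(
    dag: nx.DiGraph,
    ic: TermIC,
    genes_a: Iterable[str],
    genes_b: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
) -> Optional[float]:
    """Symmetrized best-match-average Resnik similarity between two gene sets.

    Genes with no usable annotation are dropped; if either side loses all its
    genes the comparison is unavailable (None).
    """
    a = sorted(g for g in set(genes_a) if any(t in ic.ancestors for t in annotations.get(g, ())))
    b = sorted(g for g in set(genes_b) if any(t in ic.ancestors for t in annotations.get(g, ())))
    if not a or not b:
        return None
    sim = np.array([[gene_similarity(ic, ga, gb, annotations) for gb in b] for ga in a])
    return 0.5 * (float(sim.max(axis=1).mean()) + float(sim.max(axis=0).mean()))


def genomic_similarity_matrices(
    bundle: GenomicsBundle,
    entities: Sequence[str],
    n_perm: int = 1000,
    seed: int = 0,
    overlap_method: str = OVERLAP_COEFFICIENT,
) -> SimilarityResult:
    """Aggregated genomic similarity over one entity class (drugs or diseases).

    Per pair: the PPI-module permutation p-value (smaller = more similar) and
    the Resnik set similarity (larger = more similar) are rank normalized
    separately and combined by cell-wise maximum.  One seeded RNG drives all
    permutations in sorted pair order, so results are reproducible bit for
    bit from ``seed``.
    """
    from .matrices import rank_normalize

    entities = sorted(map(str, entities))
    ic = resnik_ic(bundle.dag, bundle.annotations)
    rng = np.random.default_rng(seed)
    ppi_p: dict[tuple[str, str], Optional[float]] = {}
    res_s: dict[tuple[str, str], Optional[float]] = {}
    for a, b in combinations(entities, 2):
        ppi_p[(a, b)] = overlap_pvalue(bundle, a, b, n_perm=n_perm, rng=rng, method=overlap_method)
        res_s[(a, b)] = resnik_set_similarity(
            bundle.dag, ic, bundle.seed_sets.get(a, frozenset()),
            bundle.seed_sets.get(b, frozenset()), bundle.annotations,
        )
    ppi_sims = rank_normalize(ppi_p, SMALLER_IS_SIMILAR)
    res_sims = rank_normalize(res_s, LARGER_IS_SIMILAR)
    tables = {
        "ppi": pd.DataFrame(
            [
                (a, b, np.nan if ppi_p[(a, b)] is None else ppi_p[(a, b)], ppi_sims[(a, b)])
                for a, b in combinations(entities, 2)
            ],
            columns=["entity_a", "entity_b", "p_value", "similarity"],
        ),
        "go": pd.DataFrame(
            [
                (a, b, np.nan if res_s[(a, b)] is None else res_s[(a, b)], res_sims[(a, b)])
                for a, b in combinations(entities, 2)
            ],
            columns=["entity_a", "entity_b", "p_value", "similarity"],
        ),
    }
    aggregated = aggregate_max(entities, {"ppi": ppi_sims, "go": res_sims})
    return SimilarityResult(per_measure=tables, aggregated=aggregated)


# -- TSV / OBO readers ----------------------------------------------------


def read_ppi(path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t", dtype=str)
    g = nx.Graph()
    g.add_edges_from((a, b) for a, b in zip(df["gene_a"], df["gene_b"]) if a != b)
    return g


def read_seed_sets(path) -> dict[str, frozenset[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {
        entity: frozenset(group["gene"]) for entity, group in df.groupby("entity")
    }


def read_annotations(path) -> dict[str, frozenset[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {gene: frozenset(group["term"]) for gene, group in df.groupby("gene")}


def read_dag(path) -> nx.DiGraph:
    """Term DAG from a child/parent TSV, or from an OBO file (``.obo`` suffix)."""
    path = str(path)
    if path.endswith(".obo"):
        import obonet

        multi = obonet.read_obo(path)
        dag = nx.DiGraph()
        dag.add_nodes_from(multi.nodes)
        dag.add_edges_from(
            (c, p) for c, p, k in multi.edges(keys=True) if k == "is_a"
        )
        return dag
    df = pd.read_csv(path, sep="\t", dtype=str)
    dag = nx.DiGraph()
    dag.add_nodes_from(df["child_term"])
    dag.add_nodes_from(df["parent_term"])
    dag.add_edges_from(zip(df["child_term"], df["parent_term"]))
    return dag


def read_bundle(directory) -> GenomicsBundle:
    """Load ppi.tsv, seeds.tsv, annotations.tsv and dag.tsv from a directory."""
    from pathlib import Path

    d = Path(directory)
    return GenomicsBundle(
        ppi=read_ppi(d / "ppi.tsv"),
        seed_sets=read_seed_sets(d / "seeds.tsv"),
        dag=read_dag(d / "dag.tsv"),
        annotations=read_annotations(d / "annotations.tsv"),
    )
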