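"""Seeded generator of an EMR cohort, genomics bundle and indication network
with planted drug/disease class structure.

The generator emulates exactly the statistical structure the repositioning
model assumes: drugs and diseases come in matched classes, class-c drugs
treat class-c diseases, diseases in a class share per-test baseline lab
distributions, drugs in a class shift the same tests in the same direction,
and same-class entities share genomic modules and ontology annotations.  A
fraction of the true indications is withheld from the emitted network so
recovery can be measured against the ground truth.

``effect_size`` is the single strength knob for the planted structure: lab
baselines and drug shifts are drawn as ``effect_size`` standard deviations
per (class, test), and the per-entity seed genes come from the class gene
pool with probability min(1, effect_size / 1.5) (uniformly from the whole
gene universe otherwise), so at effect_size = 0 the cohort is exchangeable
on both channels and every downstream signal collapses to noise.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from .emr import EMRDataset, write_emr
from .genomic import GenomicsBundle
from .scoring import IndicationNetwork

#: effect_size at which the genomic class mixture saturates (seed genes drawn
#: entirely from the class pool); equals the default lab effect in SD units.
REFERENCE_EFFECT = 1.5


@dataclass
class CohortConfig:
    """Study conditions of the synthetic cohort.

    Defaults plant 4 matched drug/disease classes of 5 entities each,
    50 cases per disease, a 1.5 SD class effect on 6 laboratory tests with
    unit measurement noise, and withhold 10% of the true indications.
    """

    n_disease_classes: int = 4
    diseases_per_class: int = 5
    n_drug_classes: int = 4
    drugs_per_class: int = 5
    cases_per_disease: int = 50
    n_tests: int = 6
    effect_size: float = 1.5
    noise_sd: float = 1.0
    tests_per_case: int = 6
    stay_length: int = 14
    frac_heldout_edges: float = 0.1
    seed: int = 17
    # genomics side
    genes_per_module: int = 24
    seeds_per_entity: int = 8
    n_background_genes: int = 40
    ppi_within_p: float = 0.25
    ppi_background_p: float = 0.01
    #: fraction of an entity's seed genes drawn from its class pool at the
    #: reference effect size; curated gene sets are noisy and incomplete, so
    #: the genomic channel is deliberately weaker than the clinical one
    class_purity: float = 0.65
    #: probability a module gene is annotated to a random leaf term instead
    #: of one of its own class terms
    annotation_noise: float = 0.25

    def validate(self) -> None:
        counts = (
            self.n_disease_classes, self.diseases_per_class, self.n_drug_classes,
            self.drugs_per_class, self.cases_per_disease, self.n_tests,
            self.tests_per_case, self.stay_length, self.genes_per_module,
            self.seeds_per_entity, self.n_background_genes,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.frac_heldout_edges < 1:
            raise ValueError("frac_heldout_edges must be in [0, 1)")
        if self.tests_per_case > self.n_tests:
            raise ValueError("tests_per_case cannot exceed n_tests")
        if self.stay_length < 4:
            raise ValueError("stay_length must be >= 4 to fit a treatment window")
        if self.seeds_per_entity > self.genes_per_module:
            raise ValueError("seeds_per_entity cannot exceed genes_per_module")

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class GroundTruth:
    drug_class: dict[str, int]
    disease_class: dict[str, int]
    true_edges: frozenset[tuple[str, str]]
    held_out: frozenset[tuple[str, str]]


@dataclass
class SyntheticCohort:
    config: CohortConfig
    emr: EMRDataset
    genomics: GenomicsBundle
    network: IndicationNetwork
    truth: GroundTruth


def _treatment_windows(stay_length: int) -> list[tuple[int, int]]:
    # non-overlapping windows [2+4w, 4+4w] so each episode's lab change is
    # attributable to a single drug; at most 3 drugs per case
    windows = []
    w = 0
    while 4 + 4 * w <= stay_length and len(windows) < 3:
        windows.append((2 + 4 * w, 4 + 4 * w))
        w += 1
    return windows


def generate(config: CohortConfig) -> SyntheticCohort:
    """Draw a complete cohort; fully reproducible from ``config.seed``."""
    config.validate()
    emr_rng, gen_rng, net_rng = [
        np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(3)
    ]

    n_dis = config.n_disease_classes * config.diseases_per_class
    n_drg = config.n_drug_classes * config.drugs_per_class
    diseases = [f"D{i:03d}" for i in range(n_dis)]
    drugs = [f"R{i:03d}" for i in range(n_drg)]
    tests = [f"LAB{k}" for k in range(config.n_tests)]
    disease_class = {d: i // config.diseases_per_class for i, d in enumerate(diseases)}
    drug_class = {r: i // config.drugs_per_class for i, r in enumerate(drugs)}

    # class-level lab structure: baseline means per disease class, additive
    # treatment shifts per drug class, both in units of noise_sd
    base = config.effect_size * config.noise_sd * emr_rng.standard_normal(
        (config.n_disease_classes, config.n_tests)
    )
    shift = config.effect_size * config.noise_sd * emr_rng.standard_normal(
        (config.n_drug_classes, config.n_tests)
    )

    windows = _treatment_windows(config.stay_length)
    case_rows, rx_rows, lab_rows = [], [], []
    case_no = 0
    for disease in diseases:
        dc = disease_class[disease]
        for _ in range(config.cases_per_disease):
            case_id = f"C{case_no:06d}"
            case_no += 1
            case_rows.append((case_id, disease, 0, config.stay_length))
            n_rx = int(emr_rng.integers(1, len(windows) + 1))
            rx_drugs = emr_rng.choice(n_drg, size=n_rx, replace=False)
            if config.tests_per_case < config.n_tests:
                measured = sorted(emr_rng.choice(config.n_tests, size=config.tests_per_case, replace=False))
            else:
                measured = range(config.n_tests)
            for w, ridx in enumerate(rx_drugs):
                rx_rows.append((case_id, drugs[ridx], windows[w][0], windows[w][1]))
            for k in measured:
                mu = base[dc, k]
                for day in (0, 1):
                    lab_rows.append(
                        (case_id, tests[k], day, mu + config.noise_sd * emr_rng.standard_normal())
                    )
                for w, ridx in enumerate(rx_drugs):
                    start, end = windows[w]
                    lab_rows.append(
                        (case_id, tests[k], start, mu + config.noise_sd * emr_rng.standard_normal())
                    )
                    lab_rows.append(
                        (
                            case_id,
                            tests[k],
                            end,
                            mu + shift[drug_class[drugs[ridx]], k]
                            + config.noise_sd * emr_rng.standard_normal(),
                        )
                    )
    emr = EMRDataset.from_frames(
        pd.DataFrame(case_rows, columns=["case_id", "diagnosis", "admission_day", "discharge_day"]),
        pd.DataFrame(rx_rows, columns=["case_id", "drug", "start_day", "end_day"]),
        pd.DataFrame(lab_rows, columns=["case_id", "test", "day", "value"]),
    )

    genomics = _generate_genomics(config, gen_rng, drugs, drug_class, diseases, disease_class)

    # class-c drugs treat class-c diseases; with unequal class counts the
    # disease classes wrap around the drug classes
    true_edges = frozenset(
        (r, d)
        for r in drugs
        for d in diseases
        if drug_class[r] == disease_class[d] % config.n_drug_classes
    )
    ordered = sorted(true_edges)
    n_hold = int(np.floor(config.frac_heldout_edges * len(ordered)))
    held_idx = net_rng.choice(len(ordered), size=n_hold, replace=False) if n_hold else []
    held_out = frozenset(ordered[i] for i in held_idx)
    network = IndicationNetwork(tuple(drugs), tuple(diseases), true_edges - held_out)

    truth = GroundTruth(
        drug_class=drug_class,
        disease_class=disease_class,
        true_edges=true_edges,
        held_out=held_out,
    )
    return SyntheticCohort(config=config, emr=emr, genomics=genomics, network=network, truth=truth)


def _generate_genomics(
    config: CohortConfig,
    rng: np.random.Generator,
    drugs: list[str],
    drug_class: dict[str, int],
    diseases: list[str],
    disease_class: dict[str, int],
) -> GenomicsBundle:
    n_modules = max(config.n_drug_classes, config.n_disease_classes)
    pools = [
        [f"G{m:02d}_{g:03d}" for g in range(config.genes_per_module)]
        for m in range(n_modules)
    ]
    background = [f"GBG_{g:03d}" for g in range(config.n_background_genes)]
    all_genes = [g for pool in pools for g in pool] + background

    ppi = nx.Graph()
    ppi.add_nodes_from(all_genes)
    for pool in pools:
        for i in range(len(pool)):
            for j in range(i + 1, len(pool)):
                if rng.random() < config.ppi_within_p:
                    ppi.add_edge(pool[i], pool[j])
    for i in range(len(all_genes)):
        for j in range(i + 1, len(all_genes)):
            if rng.random() < config.ppi_background_p:
                ppi.add_edge(all_genes[i], all_genes[j])
    ppi.remove_edges_from(nx.selfloop_edges(ppi))

    # class mixture: a seed gene comes from the entity's class pool with
    # probability p_in, otherwise uniformly from the whole universe; the
    # planted genomic signal scales with effect_size and saturates at
    # class_purity (< 1: curated gene sets are never clean)
    p_in = config.class_purity * min(1.0, config.effect_size / REFERENCE_EFFECT)

    def draw_seeds(module: int) -> frozenset[str]:
        pool = pools[module]
        chosen: set[str] = set()
        while len(chosen) < config.seeds_per_entity:
            if rng.random() < p_in:
                chosen.add(pool[int(rng.integers(len(pool)))])
            else:
                chosen.add(all_genes[int(rng.integers(len(all_genes)))])
        return frozenset(chosen)

    seed_sets = {}
    for r in drugs:
        seed_sets[r] = draw_seeds(drug_class[r] % n_modules)
    for d in diseases:
        seed_sets[d] = draw_seeds(disease_class[d] % n_modules)

    dag = nx.DiGraph()
    root = "T:root"
    dag.add_node(root)
    leaves: dict[int, list[str]] = {}
    for m in range(n_modules):
        cls_term = f"T:c{m}"
        dag.add_edge(cls_term, root)
        leaves[m] = []
        for s in ("a", "b"):
            leaf = f"T:c{m}{s}"
            dag.add_edge(leaf, cls_term)
            leaves[m].append(leaf)
    dag.add_edge("T:bg", root)

    all_leaves = [leaf for m in range(n_modules) for leaf in leaves[m]]
    annotations = {}
    for m, pool in enumerate(pools):
        for g in pool:
            if rng.random() < config.annotation_noise:
                annotations[g] = frozenset({all_leaves[int(rng.integers(len(all_leaves)))]})
            else:
                annotations[g] = frozenset({leaves[m][int(rng.integers(2))]})
    for g in background:
        annotations[g] = frozenset({"T:bg"})

    return GenomicsBundle(ppi=ppi, seed_sets=seed_sets, dag=dag, annotations=annotations)


def write_bundle(cohort: SyntheticCohort, directory) -> list[Path]:
    """Emit every TSV the other modules consume, plus ground-truth side files.

    Core files: cases.tsv, prescriptions.tsv, labs.tsv, network.tsv, ppi.tsv,
    seeds.tsv, annotations.tsv, dag.tsv; side files: heldout.tsv (withheld
    true indications, disjoint from network.tsv) and truth.tsv (planted class
    labels).
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_emr(cohort.emr, d / "cases.tsv", d / "prescriptions.tsv", d / "labs.tsv")
    cohort.network.to_tsv(d / "network.tsv")
    g = cohort.genomics
    pd.DataFrame(sorted(tuple(sorted(e)) for e in g.ppi.edges), columns=["gene_a", "gene_b"]).to_csv(
        d / "ppi.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        sorted((e, gene) for e, genes in g.seed_sets.items() for gene in genes),
        columns=["entity", "gene"],
    ).to_csv(d / "seeds.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted((gene, t) for gene, terms in g.annotations.items() for t in terms),
        columns=["gene", "term"],
    ).to_csv(d / "annotations.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(g.dag.edges), columns=["child_term", "parent_term"]).to_csv(
        d / "dag.tsv", sep="\t", index=False
    )
    pd.DataFrame(sorted(cohort.truth.held_out), columns=["drug", "disease"]).to_csv(
        d / "heldout.tsv", sep="\t", index=False
    )
    truth_rows = [("drug", e, c) for e, c in sorted(cohort.truth.drug_class.items())]
    truth_rows += [("disease", e, c) for e, c in sorted(cohort.truth.disease_class.items())]
    pd.DataFrame(truth_rows, columns=["kind", "entity", "class"]).to_csv(
        d / "truth.tsv", sep="\t", index=False
    )
    return sorted(d.glob("*.tsv"))
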