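"""End-to-end orchestration: filtering -> similarity matrices -> scoring -> CV.

This is glue over the stage modules, mainly so tests, the command-line
interface and the reproduction script all run the identical pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import clinical, emr, evaluation, genomic, scoring
from .matrices import SimilarityResult
from .scoring import IndicationNetwork
from .simulate import SyntheticCohort


@dataclass
class FilterParams:
    """Cohort/test selection thresholds applied before the clinical similarities."""

    max_drugs: int = 5
    min_coverage: float = 0.40       # disease-side test coverage over cases
    min_drug_coverage: float = 0.30  # drug-side coverage over drugs
    min_cases: int = 1000            # qualifying episodes required per drug test
    min_group: int = clinical.DEFAULT_MIN_GROUP


@dataclass
class PipelineResult:
    clinical_drugs: SimilarityResult
    clinical_diseases: SimilarityResult
    genomic_drugs: SimilarityResult
    genomic_diseases: SimilarityResult
    predictions: pd.DataFrame
    cv: Optional[evaluation.CVResult] = None
    disease_tests: frozenset[str] = field(default_factory=frozenset)
    drug_tests: frozenset[str] = field(default_factory=frozenset)


def clinical_matrices(
    ds: emr.EMRDataset, params: FilterParams = FilterParams()
) -> tuple[SimilarityResult, SimilarityResult, frozenset[str], frozenset[str]]:
    """Apply the case/test filters and build both clinical similarity results."""
    ds = emr.filter_cases_by_drug_count(ds, params.max_drugs)
    disease_tests = frozenset(emr.select_disease_tests(ds, params.min_coverage))
    drug_tests = frozenset(emr.select_drug_tests(ds, params.min_drug_coverage, params.min_cases))
    dis = clinical.disease_similarity(ds, disease_tests, params.min_group)
    drg = clinical.drug_similarity(ds, drug_tests, params.min_group)
    return drg, dis, disease_tests, drug_tests


def run_pipeline(
    cohort: SyntheticCohort,
    params: FilterParams = FilterParams(),
    n_perm: int = 1000,
    theta: float = scoring.DEFAULT_THETA,
    k: int = 10,
    cv_seed: Optional[int] = None,
    run_cv: bool = True,
) -> PipelineResult:
    """Similarities, ranked predictions and (optionally) cross-validation for a cohort."""
    seed = cohort.config.seed if cv_seed is None else cv_seed
    drg, dis, disease_tests, drug_tests = clinical_matrices(cohort.emr, params)
    gen_drg = genomic.genomic_similarity_matrices(
        cohort.genomics, cohort.network.drugs, n_perm=n_perm, seed=seed
    )
    gen_dis = genomic.genomic_similarity_matrices(
        cohort.genomics, cohort.network.diseases, n_perm=n_perm, seed=seed + 1
    )
    predictions = scoring.predict(
        cohort.network, drg.aggregated, dis.aggregated,
        gen_drg.aggregated, gen_dis.aggregated, theta=theta,
    )
    cv = None
    if run_cv:
        cv = evaluation.cross_validate(
            cohort.network, drg.aggregated, dis.aggregated,
            gen_drg.aggregated, gen_dis.aggregated, k=k, seed=seed, theta=theta,
        )
    return PipelineResult(
        clinical_drugs=drg,
        clinical_diseases=dis,
        genomic_drugs=gen_drg,
        genomic_diseases=gen_dis,
        predictions=predictions,
        cv=cv,
        disease_tests=disease_tests,
        drug_tests=drug_tests,
    )


def write_results(result: PipelineResult, directory) -> None:
    """Persist every matrix, the ranked predictions and the CV table as TSV."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    result.clinical_drugs.write(d, "clin_drug")
    result.clinical_diseases.write(d, "clin_disease")
    result.genomic_drugs.write(d, "gen_drug")
    result.genomic_diseases.write(d, "gen_disease")
    result.predictions.to_csv(d / "scores.tsv", sep="\t", index=False, float_format="%.12g")
    if result.cv is not None:
        result.cv.to_frame().to_csv(d / "cv.tsv", sep="\t", index=False, float_format="%.12g")
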