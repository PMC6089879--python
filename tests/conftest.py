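"""Shared fixtures: tiny hand-built tables and seeded synthetic cohorts."""

import numpy as np
import pandas as pd
import pytest

from mdsplice.io import (
    ClinicalTable,
    CohortDesign,
    IntensityMatrix,
    PlatformAnnotation,
)
from mdsplice.simulate import SimulationConfig, simulate_study


@pytest.fixture
def tiny_annotation() -> PlatformAnnotation:
    """Two genes, three exon PSRs."""
    return PlatformAnnotation(pd.DataFrame({
        "psr_id": ["A_PSR01", "A_PSR02", "B_PSR01"],
        "gene_id": ["GA", "GA", "GB"],
        "exon_index": [1, 2, 1],
        "biotype": ["coding", "coding", "non_coding"],
        "chrom": ["chr1", "chr1", "chr2"],
        "start": [100, 500, 100],
        "end": [250, 650, 250],
        "region_kind": ["exon_psr", "exon_psr", "exon_psr"],
    }))


@pytest.fixture
def tiny_clinical() -> ClinicalTable:
    return ClinicalTable(pd.DataFrame({
        "sample_id": ["P1", "C1", "C2"],
        "cohort": ["patient", "control", "control"],
        "os_time": [12.0, 60.0, 60.0],
        "os_event": [1, 0, 0],
        "ttlc_time": [12.0, 60.0, 60.0],
        "ttlc_event": [0, 0, 0],
        "sex_male": [1, 0, 1],
    }))


def make_matrix(values: dict, psr_ids) -> IntensityMatrix:
    """values: sample_id -> list of intensities (ordered by psr_ids)."""
    return IntensityMatrix(pd.DataFrame(
        values, index=pd.Index(psr_ids, name="psr_id")).astype(float))


@pytest.fixture
def worked_example():
    """One gene, two PSRs: patient PSR 50 with gene level 100 against a flat
    control reference of 100 -> linear ratio 0.5, converted SI -2."""
    ann = PlatformAnnotation(pd.DataFrame({
        "psr_id": ["GA_PSR01", "GA_PSR02"],
        "gene_id": ["GA", "GA"],
        "exon_index": [1, 2],
        "biotype": ["coding", "coding"],
        "chrom": ["chr1", "chr1"],
        "start": [0, 400],
        "end": [150, 550],
        "region_kind": ["exon_psr", "exon_psr"],
    }))
    m = make_matrix({"P1": [50.0, 150.0], "C1": [100.0, 100.0],
                     "C2": [100.0, 100.0]}, ["GA_PSR01", "GA_PSR02"])
    design = CohortDesign(("P1",), ("C1", "C2"))
    return m, ann, design


# Cohort-scale fixtures -------------------------------------------------------

@pytest.fixture(scope="session")
def exact_study():
    """Zero-noise cohort with planted folds {4, 1/4} and boundary folds
    {1.8, 2.0}: the planted splicing indices are exact in float arithmetic."""
    cfg = SimulationConfig(
        n_genes=50, n_patients=20, n_controls=5, n_validation=0,
        noise_log2_sigma=0.0, seed=7, n_prognostic_events=0,
        fold_change_set=(4.0, 0.25), nonconforming_fold_set=(1.8, 2.0),
        nonconforming_rate=0.15, aberrant_gene_rate=0.3)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def noisy_study():
    """Small noisy cohort with survival structure, for pipeline-level tests."""
    cfg = SimulationConfig(
        n_genes=60, n_patients=40, n_controls=8, n_validation=15,
        n_prognostic_events=5, seed=5)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def noisy_study_files(noisy_study, tmp_path_factory):
    """The noisy cohort written out in the documented file dialects."""
    from mdsplice.io import (write_clinical_table, write_intensity_matrix,
                             write_platform_annotation)
    from mdsplice.simulate import export_truth

    root = tmp_path_factory.mktemp("simdata")
    write_platform_annotation(noisy_study.annotation, root / "annotation.tsv")
    write_intensity_matrix(noisy_study.intensities, root / "intensities.tsv")
    write_clinical_table(noisy_study.clinical, root / "clinical.csv")
    export_truth(noisy_study.truth, root / "truth.tsv")
    return root
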