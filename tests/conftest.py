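"""Shared fixtures: small synthetic cohorts with known planted signals."""

import logging

import numpy as np
import pytest

from silentmut.cohort_io import MutationCategory, filter_patients
from silentmut.feature_engineering import build_all_datasets
from silentmut.synthetic_cohort import (
    CohortConfig,
    SignatureSpec,
    gene_count_signal,
    make_annotation,
    point_signal,
    simulate_cohort,
)

logging.getLogger("silentmut").setLevel(logging.ERROR)

# Quiet LightGBM-on-sparse feature-name chatter in sklearn validation.
import warnings

warnings.filterwarnings("ignore", message="X does not have valid feature names")


@pytest.fixture(scope="session")
def annotation():
    return make_annotation(10, seed=11)


@pytest.fixture(scope="session")
def small_cohort(annotation):
    """3 synthetic cancer types x 60 patients with planted signals.

    Each type plants one recurrent non-silent point mutation and one
    intronic gene-count signal at prevalence 0.4 in type-specific genes.
    """
    signatures = []
    for t in range(3):
        ctype = f"T{t + 1:02d}"
        signatures.append(
            SignatureSpec(
                cancer_type=ctype,
                signals=(
                    point_signal(
                        f"{ctype}_ns", annotation[2 * t].gene_symbol,
                        MutationCategory.NON_SILENT, 0.4,
                    ),
                    gene_count_signal(
                        f"{ctype}_intron", annotation[2 * t + 1].gene_symbol,
                        MutationCategory.INTRON, 0.4,
                    ),
                ),
            )
        )
    config = CohortConfig(
        patients_per_type=60,
        background_rates={c: 2.0 for c in MutationCategory},
        seed=202,
    )
    mutations, clinical, truth = simulate_cohort(annotation, signatures, config)
    mutations, clinical, _ = filter_patients(mutations, clinical)
    return mutations, clinical, truth, signatures


@pytest.fixture(scope="session")
def small_datasets(annotation, small_cohort):
    mutations, clinical, _, _ = small_cohort
    patients = sorted(clinical["patient_id"])
    return build_all_datasets(mutations, annotation, patients), patients


@pytest.fixture(scope="session")
def dense_cohort():
    """2 types x 80 patients on a compact genome: positions recur, so every
    category (including flank) yields high-resolution features."""
    annotation = make_annotation(4, seed=23, flank_length=60, region_scale=0.3)
    signatures = [
        SignatureSpec(
            "D01", (point_signal("d1", "G001", MutationCategory.NON_SILENT, 0.4),)
        ),
        SignatureSpec(
            "D02", (point_signal("d2", "G002", MutationCategory.NON_SILENT, 0.4),)
        ),
    ]
    config = CohortConfig(
        patients_per_type=80,
        background_rates={
            MutationCategory.NON_SILENT: 6.0,
            MutationCategory.INTRON: 4.0,
            MutationCategory.UTR: 3.0,
            MutationCategory.SYNONYMOUS: 3.0,
            MutationCategory.FLANK: 2.0,
        },
        seed=31,
    )
    mutations, clinical, truth = simulate_cohort(annotation, signatures, config)
    patients = sorted(clinical["patient_id"])
    datasets = build_all_datasets(mutations, annotation, patients)
    return annotation, mutations, clinical, datasets, patients


def random_cohort(rng, annotation, n_patients, n_mutations):
    """Random mutations drawn directly from annotated regions (no signals)."""
    from silentmut.synthetic_cohort import CATEGORY_REGIONS, _random_mutation

    patients = [f"P{i:03d}" for i in range(n_patients)]
    records = []
    cats = list(MutationCategory)
    for _ in range(n_mutations):
        pid = patients[int(rng.integers(n_patients))]
        gene = annotation[int(rng.integers(len(annotation)))]
        cat = cats[int(rng.integers(len(cats)))]
        vt = ["SNP", "DEL", "INS"][int(rng.integers(3))]
        records.append(_random_mutation(rng, pid, gene, cat, vt))
    return patients, records
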