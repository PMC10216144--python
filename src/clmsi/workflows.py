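"""End-to-end convenience pipelines used by the drivers and acceptance runs.

These wire together the generator, annotation chain, and statistics exactly
as the module APIs expose them: generate → per-pixel annotate → per-patient
median S/N → richness / chain ratio.
"""

from __future__ import annotations

import pandas as pd

from .annotate import AnnotationConfig
from .chem import default_species_space
from .imaging import RegionMask, extract_region_snr, per_patient_median
from .profiling import chain_ratio, species_richness
from .synthetic import GeneratorConfig, generate_cohort, generate_imaging_dataset

__all__ = ["detected_species_counts", "cohort_chain_ratios", "cohort_profile_matrix"]


def detected_species_counts(
    config: GeneratorConfig,
    annotation: AnnotationConfig = AnnotationConfig(),
) -> dict[str, int]:
    """Generate one section and count detected CL and MLCL species.

    A species counts as detected when its across-pixel median S/N reaches
    the detection threshold — the same per-sample statistic the profile
    matrix is built from.
    """
    dataset, _ = generate_imaging_dataset(config)
    mask = RegionMask(config.layout_array())
    label = str(config.layout_array()[0, 0])
    space = default_species_space()
    table = extract_region_snr(dataset, mask, label, space, annotation)
    matrix = per_patient_median({"section": table}, {"section": label})
    return {
        "CL": int(species_richness(matrix, annotation.snr_threshold, "CL").iloc[0]),
        "MLCL": int(species_richness(matrix, annotation.snr_threshold, "MLCL").iloc[0]),
    }


def cohort_profile_matrix(
    tissue_class: str,
    n_patients: int,
    config: GeneratorConfig,
    annotation: AnnotationConfig = AnnotationConfig(),
):
    """Generate and annotate a single-class cohort; return its ProfileMatrix."""
    cohort = generate_cohort(tissue_class, n_patients, config)
    space = default_species_space()
    tables, labels = {}, {}
    for record in cohort:
        tables[record["patient"]] = extract_region_snr(
            record["dataset"], record["mask"], tissue_class, space, annotation
        )
        labels[record["patient"]] = tissue_class
    return per_patient_median(tables, labels)


def cohort_chain_ratios(
    tissue_class: str,
    n_patients: int,
    config: GeneratorConfig,
    annotation: AnnotationConfig = AnnotationConfig(),
) -> pd.Series:
    """Per-patient long/short chain S/N ratios for a synthetic cohort."""
    matrix = cohort_profile_matrix(tissue_class, n_patients, config, annotation)
    ratios, _ = chain_ratio(matrix)
    return ratios
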