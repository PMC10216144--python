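"""Synthetic DESI-FAIMS imaging data with tissue-class CL profile structure.

The generator emulates the statistical structure of cardiolipin profiles in
human brain sections:

* normal grey matter (``NL_grey``) carries a 46-species CL panel spanning
  68–80 acyl carbons and 2–14 double bonds, organized in carbon-number
  clusters of ~0.5-m/z-spaced doubly charged ions; within-cluster
  abundances are unimodal and the global mode is CL(74:8);
* lower-grade astrocytoma (``AST1``/``AST2``) keeps the cluster structure at
  lower overall abundance; glioblastoma (``GBM``) loses the long-chain
  clusters entirely (CL(76:10), CL(78:12) absent) and its mode shifts to
  CL(72:6);
* the long/short chain-length marker — the abundance of CL(78:12) relative
  to CL(72:8) — is calibrated per class to the reported tissue-type ratios
  0.48 (NL), 0.05 (AST grade 1), 0.10 (AST grade 2); GBM carries no
  CL(78:12) at all, so its measured ratio is ≈ 0 (reported ≈ 0.01);
* pure white matter has no detectable CL (ion suppression by myelin
  lipids) and necrotic tumor is attenuated to 20% of viable tumor;
* each species contributes its z = −2 isotope envelope as Gaussian peaks at
  resolving power 70,000 over m/z 100–1500, on a Gaussian baseline noise
  floor.

Ground truth (region labels, per-class abundances, calibrated expected
ratios) is emitted alongside every dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import FattyAcyl, LipidSpecies, diagnostic_pair_mz, isotope_envelope
from .imaging import TISSUE_CLASSES, ImagingDataset, RegionMask

__all__ = [
    "TissueClassProfile",
    "GeneratorConfig",
    "build_profile",
    "render_spectrum",
    "generate_imaging_dataset",
    "generate_cohort",
    "generate_uvpd_peaklist",
    "NL_PANEL_SIZES",
    "CHAIN_RATIO_TARGETS",
]

# Within-cluster double-bond ranges and modes per carbon number:
# carbons -> (db_min, db_max, db_mode).  The NL panel has
# 4+6+8+10+8+6+4 = 46 CL species; the mode sits at CL(74:8).
_NL_CLUSTERS: Mapping[int, tuple[int, int, float]] = {
    68: (2, 5, 3.5),
    70: (2, 7, 4.5),
    72: (2, 9, 6.0),
    74: (4, 13, 8.0),
    76: (6, 13, 10.0),
    78: (9, 14, 11.5),
    80: (11, 14, 12.5),
}
# AST keeps the NL structure without the 80-carbon tail cluster.
_AST_CLUSTERS = {x: v for x, v in _NL_CLUSTERS.items() if x <= 78}
# GBM loses the long-chain clusters entirely and narrows the rest.
_GBM_CLUSTERS: Mapping[int, tuple[int, int, float]] = {
    68: (2, 5, 3.0),
    70: (2, 7, 4.0),
    72: (3, 8, 6.0),
    74: (5, 9, 7.0),
}

# 12 MLCL species seen alongside the CL panel in normal cortex.
_MLCL_PANEL: tuple[tuple[int, int], ...] = (
    (50, 1), (50, 2), (52, 2), (52, 3), (54, 4), (54, 5),
    (56, 5), (56, 6), (58, 7), (58, 8), (60, 8), (60, 9),
)
_MLCL_FRACTION = 0.35  # peak MLCL weight relative to the peak CL weight

_CLUSTERS = {
    "NL_grey": _NL_CLUSTERS,
    "AST1": _AST_CLUSTERS,
    "AST2": _AST_CLUSTERS,
    "GBM": _GBM_CLUSTERS,
}
_CARBON_CENTER = {"NL_grey": 74.0, "AST1": 73.0, "AST2": 73.0, "GBM": 72.0}
_CARBON_SD = {"NL_grey": 6.0, "AST1": 6.0, "AST2": 6.0, "GBM": 5.0}

#: Expected long/short S/N ratio S/N(CL 78:12)/S/N(CL 72:8) per tissue class.
CHAIN_RATIO_TARGETS = {"NL_grey": 0.48, "AST1": 0.05, "AST2": 0.10, "GBM": 0.01}

#: Overall abundance multiplier per class (viable GBM = 0.4 of NL; necrosis
#: is a further ×0.2 of viable tumor).
_ATTENUATION = {
    "NL_grey": 1.0,
    "NL_white": 1.0,
    "AST1": 0.6,
    "AST2": 0.6,
    "GBM": 0.4,
    "infiltrating": 0.55,
    "necrotic": 0.4 * 0.2,
}

NL_PANEL_SIZES = {"CL": 46, "MLCL": 12}

_LONG = LipidSpecies("CL", 78, 12)
_SHORT = LipidSpecies("CL", 72, 8)


@dataclass(frozen=True)
class TissueClassProfile:
    """Relative species abundances (summing to 1) for one tissue class."""

    tissue_class: str
    species_abundance: Mapping[LipidSpecies, float]
    attenuation: float
    expected_chain_ratio: float | None = None

    def __post_init__(self):
        if any(a < 0 for a in self.species_abundance.values()):
            raise ValueError("abundances must be non-negative")
        total = sum(self.species_abundance.values())
        if self.species_abundance and not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError("abundances must sum to 1 before attenuation")


def _cluster_weights(
    clusters: Mapping[int, tuple[int, int, float]],
    carbon_center: float,
    carbon_sd: float,
) -> dict[LipidSpecies, float]:
    weights: dict[LipidSpecies, float] = {}
    for x, (y_min, y_max, y_mode) in clusters.items():
        xw = math.exp(-(((x - carbon_center) / carbon_sd) ** 2))
        y_sd = (y_max - y_min) / 2.0
        for y in range(y_min, y_max + 1):
            yw = math.exp(-(((y - y_mode) / y_sd) ** 2))
            weights[LipidSpecies("CL", x, y)] = xw * yw
    return weights


def _expected_apex_height(
    weights: Mapping[LipidSpecies, float],
    species: LipidSpecies,
    resolving_power: float,
    isotope_peaks: int,
) -> float:
    """Expected noiseless peak height at a species' [M−2H]²⁻ apex.

    At resolving power 70,000 the M+2 isotopologue of the cluster neighbour
    one double bond up merges into a species' monoisotopic peak (4.5 mDa
    apart, FWHM ≈ 10 mDa), so the measured apex height is the superposition
    of every nearby envelope Gaussian — not the bare abundance.  Evaluated
    in closed form on a fine local grid.
    """
    m0 = species.mz_2minus
    grid = np.linspace(m0 - 0.006, m0 + 0.006, 25)
    total = np.zeros_like(grid)
    for other, weight in weights.items():
        if weight <= 0 or abs(other.mz_2minus - m0) > 3.0:
            continue
        envelope = _cached_envelope(other, isotope_peaks)
        for peak_mz, rel in zip(envelope.mz, envelope.abundance):
            if abs(peak_mz - m0) > 0.05:
                continue
            sigma = (peak_mz / resolving_power) / 2.3548200450309493
            total += weight * rel * np.exp(-0.5 * ((grid - peak_mz) / sigma) ** 2)
    return float(total.max())


def build_profile(
    tissue_class: str,
    resolving_power: float = 70_000.0,
    isotope_peaks: int = 4,
) -> TissueClassProfile:
    """Construct the CL/MLCL abundance profile of one tissue class.

    The long-chain (≥78-carbon) clusters are rescaled as a block so that
    the *expected measured* S/N ratio CL(78:12)/CL(72:8) — apex heights
    under the forward model, including the isotopologue interference from
    unresolved cluster neighbours — hits the class target, while preserving
    within-cluster unimodality.  Pure white matter gets an empty profile;
    infiltrating tumor is an even mixture of normal-cortex and GBM
    profiles; necrotic tissue is the GBM profile at 20% abundance.
    """
    if tissue_class not in TISSUE_CLASSES:
        raise ValueError(f"unknown tissue class {tissue_class!r}")
    attenuation = _ATTENUATION[tissue_class]
    if tissue_class == "NL_white":
        return TissueClassProfile(tissue_class, {}, attenuation)
    if tissue_class == "necrotic":
        base = build_profile("GBM", resolving_power, isotope_peaks)
        return TissueClassProfile(
            tissue_class, base.species_abundance, attenuation, base.expected_chain_ratio
        )
    if tissue_class == "infiltrating":
        nl = build_profile("NL_grey", resolving_power, isotope_peaks).species_abundance
        gbm = build_profile("GBM", resolving_power, isotope_peaks).species_abundance
        mixed = {sp: 0.5 * nl.get(sp, 0.0) + 0.5 * gbm.get(sp, 0.0)
                 for sp in set(nl) | set(gbm)}
        total = sum(mixed.values())
        mixed = {sp: a / total for sp, a in mixed.items()}
        ratio = mixed.get(_LONG, 0.0) / mixed[_SHORT]
        return TissueClassProfile(tissue_class, mixed, attenuation, ratio)

    weights = _cluster_weights(
        _CLUSTERS[tissue_class], _CARBON_CENTER[tissue_class], _CARBON_SD[tissue_class]
    )
    target = CHAIN_RATIO_TARGETS[tissue_class]
    if _LONG in weights:
        # Scale the whole long-chain tail so the expected measured apex
        # ratio equals the class target without breaking intra-cluster
        # unimodality.  Interference at the CL(78:12) apex comes only from
        # the ≥78-carbon block itself (which scales with it) and at the
        # CL(72:8) apex only from the shorter-chain block, so the block
        # factor has a closed-form solution.
        long_block = {s: w for s, w in weights.items() if s.total_carbons >= 78}
        short_block = {s: w for s, w in weights.items() if s.total_carbons < 78}
        long_apex = _expected_apex_height(
            long_block, _LONG, resolving_power, isotope_peaks
        )
        short_apex = _expected_apex_height(
            short_block, _SHORT, resolving_power, isotope_peaks
        )
        factor = target * short_apex / long_apex
        for sp in long_block:
            weights[sp] *= factor
        expected_ratio = target
    else:
        expected_ratio = 0.0  # GBM: CL(78:12) genuinely absent
    for i, (x, y) in enumerate(_MLCL_PANEL):
        mw = _MLCL_FRACTION * math.exp(-(((i - 5.5) / 6.0) ** 2))
        weights[LipidSpecies("MLCL", x, y)] = mw
    total = sum(weights.values())
    abundances = {sp: w / total for sp, w in weights.items()}
    return TissueClassProfile(tissue_class, abundances, attenuation, expected_ratio)


@dataclass(frozen=True)
class GeneratorConfig:
    """Acquisition and noise parameters of the synthetic imaging run.

    Defaults mirror the emulated acquisition: negative mode, m/z 100–1500
    at resolving power 70,000, 20×20 pixel sections.  ``seed`` fully
    determines the truth tables (profiles and between-patient jitter);
    ``noise_seed`` (derived from ``seed`` when not given) drives only the
    baseline noise, so re-rolling noise never changes the ground truth.
    """

    rows: int = 20
    cols: int = 20
    layout: tuple[tuple[str, ...], ...] | None = None  # None → uniform NL_grey
    resolving_power: float = 70_000.0
    mz_min: float = 100.0
    mz_max: float = 1500.0
    mz_step: float = 0.003
    baseline_mean: float = 0.0
    noise_sd: float = 1.0
    intensity_scale: float = 6000.0
    isotope_peaks: int = 4
    jitter_cv: float = 0.15
    seed: int = 0
    noise_seed: int | None = None

    def __post_init__(self):
        if self.resolving_power <= 0:
            raise ValueError("resolving power must be positive")
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid dimensions must be positive")

    def mz_axis(self) -> np.ndarray:
        return np.arange(self.mz_min, self.mz_max, self.mz_step)

    def layout_array(self) -> np.ndarray:
        if self.layout is None:
            return np.full((self.rows, self.cols), "NL_grey", dtype=object)
        layout = np.asarray(self.layout, dtype=object)
        if layout.shape != (self.rows, self.cols):
            raise ValueError(
                f"layout shape {layout.shape} does not cover the "
                f"{self.rows}x{self.cols} grid"
            )
        return layout

    def effective_noise_seed(self) -> int:
        if self.noise_seed is not None:
            return self.noise_seed
        return (self.seed + 982_451_653) % (2**31)


def _jittered(
    profile: TissueClassProfile, config: GeneratorConfig, rng: np.random.Generator
) -> dict[LipidSpecies, float]:
    """Between-patient biological variability: per-species log-normal
    multipliers with unit mean and the configured CV."""
    abundances = dict(profile.species_abundance)
    if config.jitter_cv > 0 and abundances:
        sigma2 = math.log(1.0 + config.jitter_cv**2)
        multipliers = rng.lognormal(
            mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=len(abundances)
        )
        abundances = {
            sp: a * m for (sp, a), m in zip(abundances.items(), multipliers)
        }
    return abundances


@lru_cache(maxsize=512)
def _cached_envelope(species: LipidSpecies, k: int):
    return isotope_envelope(species.neutral_formula, z=-2, k=k)


def render_spectrum(
    profile: TissueClassProfile,
    config: GeneratorConfig,
    rng: np.random.Generator,
    abundances: Mapping[LipidSpecies, float] | None = None,
    mz_axis: np.ndarray | None = None,
) -> np.ndarray:
    """Render one profile-mode spectrum (float32 intensities).

    Each species contributes its z = −2 isotope envelope as Gaussian peaks
    of FWHM = m/z / R, with peak height proportional to abundance ×
    attenuation × ``intensity_scale``; Gaussian baseline noise is added.
    """
    mz = config.mz_axis() if mz_axis is None else mz_axis
    intensity = rng.normal(config.baseline_mean, config.noise_sd, size=len(mz))
    if abundances is None:
        abundances = profile.species_abundance
    for species, abundance in abundances.items():
        if abundance <= 0:
            continue
        envelope = _cached_envelope(species, config.isotope_peaks)
        for peak_mz, rel in zip(envelope.mz, envelope.abundance):
            if not (mz[0] < peak_mz < mz[-1]):
                continue
            height = abundance * profile.attenuation * config.intensity_scale * rel
            sigma = (peak_mz / config.resolving_power) / 2.3548200450309493
            i0, i1 = np.searchsorted(mz, [peak_mz - 5 * sigma, peak_mz + 5 * sigma])
            window = mz[i0:i1]
            intensity[i0:i1] += height * np.exp(
                -0.5 * ((window - peak_mz) / sigma) ** 2
            )
    return intensity.astype(np.float32)


def generate_imaging_dataset(
    config: GeneratorConfig,
) -> tuple[ImagingDataset, dict[str, pd.DataFrame]]:
    """Generate one section: a pixel grid of spectra plus ground truth.

    Returns the dataset and truth tables: ``pixels`` (per-pixel region
    label), ``abundances`` (per-class post-jitter species abundances) and
    ``expected_ratios`` (the calibrated per-class chain-ratio targets).
    The jitter here is the per-section (per-patient) draw.
    """
    layout = config.layout_array()
    truth_rng = np.random.default_rng(config.seed)
    noise_rng = np.random.default_rng(config.effective_noise_seed())
    classes = sorted({str(label) for label in layout.ravel()})
    profiles = {
        name: build_profile(name, config.resolving_power, config.isotope_peaks)
        for name in classes
    }
    abundances = {
        name: _jittered(profiles[name], config, truth_rng) for name in classes
    }
    mz = config.mz_axis()
    intensities = np.empty((config.rows, config.cols, len(mz)), dtype=np.float32)
    for r in range(config.rows):
        for c in range(config.cols):
            name = str(layout[r, c])
            intensities[r, c] = render_spectrum(
                profiles[name], config, noise_rng, abundances[name], mz_axis=mz
            )
    metadata = {
        "polarity": "negative",
        "resolving_power": config.resolving_power,
        "mz_range": (config.mz_min, config.mz_max),
        "pixel_size_um": 200.0,
        "seed": config.seed,
    }
    dataset = ImagingDataset(mz=mz, intensities=intensities, metadata=metadata)
    pixel_rows = [
        {"row": r, "col": c, "label": str(layout[r, c])}
        for r in range(config.rows)
        for c in range(config.cols)
    ]
    abundance_rows = [
        {
            "tissue_class": name,
            "species": sp.name,
            "abundance": value,
            "attenuation": profiles[name].attenuation,
        }
        for name in classes
        for sp, value in sorted(abundances[name].items(), key=lambda kv: kv[0].mz_2minus)
    ]
    ratio_rows = [
        {"tissue_class": name, "expected_chain_ratio": profiles[name].expected_chain_ratio}
        for name in classes
        if profiles[name].expected_chain_ratio is not None
    ]
    truth = {
        "pixels": pd.DataFrame(pixel_rows),
        "abundances": pd.DataFrame(abundance_rows),
        "expected_ratios": pd.DataFrame(ratio_rows),
    }
    return dataset, truth


def generate_cohort(
    tissue_class: str,
    n_patients: int,
    config: GeneratorConfig,
    seed: int | None = None,
) -> list[dict]:
    """Generate a cohort of single-region patients of one tissue class.

    Each patient is one small section rendered from an independently
    jittered copy of the class profile.  Returns a list of records with
    ``patient``, ``tissue_class``, ``dataset``, ``mask`` and ``truth``.
    """
    base_seed = config.seed if seed is None else seed
    layout = tuple(tuple(tissue_class for _ in range(config.cols))
                   for _ in range(config.rows))
    cohort = []
    for i in range(n_patients):
        patient_config = replace(
            config, layout=layout, seed=(base_seed + 7919 * i) % (2**31),
            noise_seed=None,
        )
        dataset, truth = generate_imaging_dataset(patient_config)
        mask = RegionMask(patient_config.layout_array())
        cohort.append(
            {
                "patient": f"{tissue_class}_{i:03d}",
                "tissue_class": tissue_class,
                "dataset": dataset,
                "mask": mask,
                "truth": truth,
            }
        )
    return cohort


def generate_uvpd_peaklist(
    ratio_delta9_to_delta11: float,
    n_ions_per_isomer: int = 2,
    noise_cv: float = 0.0,
    seed: int = 0,
    base_intensity: float = 1000.0,
) -> dict:
    """Centroid UVPD peak list with a known Δ9/Δ11 diagnostic-ion ratio.

    The Δ9 and Δ11 diagnostic pairs of FA 18:1 are emitted with summed
    intensities in the requested ratio (split 60/40 within each pair),
    optionally perturbed by multiplicative log-normal noise of the given
    CV.  Returns the peak list plus the two diagnostic ion sets.
    """
    if ratio_delta9_to_delta11 <= 0:
        raise ValueError("isomer ratio must be positive")
    if n_ions_per_isomer != 2:
        raise ValueError("diagnostic pairs have exactly two ions per isomer")
    rng = np.random.default_rng(seed)
    ions_d9 = diagnostic_pair_mz(FattyAcyl(18, 1, (9,)))
    ions_d11 = diagnostic_pair_mz(FattyAcyl(18, 1, (11,)))
    split = np.array([0.6, 0.4])
    intensity = np.concatenate(
        [
            base_intensity * ratio_delta9_to_delta11 * split,
            base_intensity * split,
        ]
    )
    if noise_cv > 0:
        sigma2 = math.log(1.0 + noise_cv**2)
        intensity = intensity * rng.lognormal(
            -sigma2 / 2.0, math.sqrt(sigma2), size=intensity.size
        )
    return {
        "mz": np.concatenate([ions_d9, ions_d11]),
        "intensity": intensity,
        "ions_delta9": ions_d9,
        "ions_delta11": ions_d11,
    }
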