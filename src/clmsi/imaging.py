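"""Imaging dataset container, imzML I/O, region masks, and ion images.

Datasets are continuous-mode: one shared m/z axis for every pixel, which is
what the synthetic generator produces and what the imzML writer emits.
Processed-mode files (per-pixel axes) are rejected loudly on read.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import AnnotationConfig, annotate_spectrum
from .chem import LipidSpecies

__all__ = [
    "Spectrum",
    "ImagingDataset",
    "RegionMask",
    "IonImage",
    "read_imzml",
    "write_imzml",
    "ion_image",
    "extract_region_snr",
    "per_patient_median",
    "ProfileMatrix",
]

#: Tissue-class vocabulary used in region masks.
TISSUE_CLASSES = (
    "NL_grey",
    "NL_white",
    "AST1",
    "AST2",
    "GBM",
    "infiltrating",
    "necrotic",
)
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class Spectrum:
    """Paired m/z and intensity arrays; profile or centroid mode."""

    mz: np.ndarray
    intensity: np.ndarray
    mode: str = "profile"

    def __post_init__(self):
        if len(self.mz) != len(self.intensity):
            raise ValueError("m/z and intensity arrays must have equal length")


@dataclass
class ImagingDataset:
    """A pixel grid of profile spectra sharing one m/z axis.

    ``intensities`` has shape (rows, cols, n_mz); coordinates are 0-based,
    row-major (row, col).  ``metadata`` records acquisition provenance
    (polarity, resolving power, m/z range, pixel size).
    """

    mz: np.ndarray
    intensities: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a (rows, cols, n_mz) array")
        if self.intensities.shape[2] != len(self.mz):
            raise ValueError("m/z axis length does not match intensity arrays")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape[:2]

    def spectrum(self, row: int, col: int) -> Spectrum:
        return Spectrum(self.mz, self.intensities[row, col])

    def pixels(self):
        rows, cols = self.shape
        for r in range(rows):
            for c in range(cols):
                yield r, c


@dataclass
class RegionMask:
    """Per-pixel tissue-class labels (plus ``unassigned``)."""

    labels: np.ndarray  # 2-D array of label strings

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.ndim != 2:
            raise ValueError("mask labels must form a 2-D grid")
        vocabulary = set(TISSUE_CLASSES) | {UNASSIGNED}
        bad = {l for l in self.labels.ravel() if l not in vocabulary}
        if bad:
            raise ValueError(f"unknown tissue-class labels in mask: {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def pixels_with(self, label: str) -> list[tuple[int, int]]:
        rows, cols = np.nonzero(self.labels == label)
        return list(zip(rows.tolist(), cols.tolist()))

    # Masks travel as an integer-label CSV grid plus a JSON label map, so
    # they can be produced by any annotation tool (or a text editor).
    def to_csv(self, grid_path: str | Path, labelmap_path: str | Path) -> None:
        labels = sorted({l for l in self.labels.ravel()})
        code = {label: i for i, label in enumerate(labels)}
        grid = np.vectorize(code.get)(self.labels)
        np.savetxt(grid_path, grid, fmt="%d", delimiter=",")
        Path(labelmap_path).write_text(
            json.dumps({str(i): label for label, i in code.items()}, indent=1)
        )

    @classmethod
    def from_csv(cls, grid_path: str | Path, labelmap_path: str | Path) -> "RegionMask":
        grid = np.loadtxt(grid_path, dtype=int, delimiter=",", ndmin=2)
        mapping = json.loads(Path(labelmap_path).read_text())
        labels = np.vectorize(lambda i: mapping[str(int(i))])(grid).astype(object)
        return cls(labels)


@dataclass(frozen=True)
class IonImage:
    """2-D intensity map for one target m/z window."""

    values: np.ndarray
    target_mz: float
    tol_ppm: float


def _check_same_shape(dataset: ImagingDataset, mask: RegionMask) -> None:
    if dataset.shape != mask.shape:
        raise ValueError(
            f"dataset grid {dataset.shape} and mask grid {mask.shape} disagree"
        )


def write_imzml(dataset: ImagingDataset, path: str | Path) -> None:
    """Write a continuous-mode negative-polarity imzML file (plus .ibd)."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    path = str(path)
    with ImzMLWriter(path, mode="continuous", polarity="negative") as writer:
        for r, c in dataset.pixels():
            # imzML coordinates are 1-based (x = column, y = row).
            writer.addSpectrum(dataset.mz, dataset.intensities[r, c], (c + 1, r + 1))


def read_imzml(path: str | Path) -> ImagingDataset:
    """Read a continuous-mode imzML file into an :class:`ImagingDataset`.

    Processed-mode files are rejected, naming the offending declaration's
    position in the XML; a missing pixel inside the coordinate bounding box
    is an error.
    """
    path = Path(path)
    text = path.read_text(errors="ignore")
    processed = re.search(r'name="processed"', text)
    if processed and not re.search(r'name="continuous"', text):
        raise ValueError(
            f"{path} declares processed-mode data (file offset {processed.start()}); "
            "only continuous-mode imzML is supported"
        )
    from pyimzml.ImzMLParser import ImzMLParser

    parser = ImzMLParser(str(path))
    coords = [(x, y) for x, y, *_ in parser.coordinates]
    if not coords:
        raise ValueError(f"{path} contains no spectra")
    xs = [x for x, _ in coords]
    ys = [y for _, y in coords]
    rows = max(ys) - min(ys) + 1
    cols = max(xs) - min(xs) + 1
    if len(coords) != rows * cols or len(set(coords)) != len(coords):
        raise ValueError(
            f"{path}: pixel coordinates do not tile a full {rows}x{cols} grid"
        )
    mz0, _ = parser.getspectrum(0)
    mz0 = np.asarray(mz0, dtype=float)
    intensities = np.zeros((rows, cols, len(mz0)), dtype=np.float32)
    for i, (x, y) in enumerate(coords):
        mz_i, intensity = parser.getspectrum(i)
        if len(mz_i) != len(mz0):
            raise ValueError(f"{path}: spectrum {i} has a private m/z axis")
        intensities[y - min(ys), x - min(xs)] = intensity
    metadata = {"polarity": "negative", "source": str(path)}
    return ImagingDataset(mz=mz0, intensities=intensities, metadata=metadata)


def ion_image(dataset: ImagingDataset, target_mz: float, tol_ppm: float) -> IonImage:
    """Per-pixel maximum profile intensity within ``target_mz ± tol_ppm``."""
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    mz = dataset.mz
    if not mz[0] <= target_mz <= mz[-1]:
        raise ValueError(
            f"target m/z {target_mz} outside acquisition range "
            f"({mz[0]:.1f}–{mz[-1]:.1f})"
        )
    tol = tol_ppm * 1e-6 * target_mz
    i0, i1 = np.searchsorted(mz, [target_mz - tol, target_mz + tol])
    if i1 <= i0:
        values = np.zeros(dataset.shape)
    else:
        values = dataset.intensities[:, :, i0:i1].max(axis=2).astype(float)
    return IonImage(values=values, target_mz=target_mz, tol_ppm=tol_ppm)


def extract_region_snr(
    dataset: ImagingDataset,
    mask: RegionMask,
    label: str,
    species_list: Sequence[LipidSpecies],
    config: AnnotationConfig = AnnotationConfig(),
) -> pd.DataFrame:
    """Per-pixel, per-species S/N table for one region label.

    Each in-region pixel spectrum is run through the annotation chain; a
    species with no surviving annotation in a pixel contributes S/N 0 (not
    a missing value), so downstream medians are always defined.
    """
    _check_same_shape(dataset, mask)
    pixels = mask.pixels_with(label)
    if not pixels:
        raise ValueError(f"label {label!r} is absent from the mask")
    space = sorted(species_list, key=lambda s: s.mz_2minus)
    names = [s.name for s in space]
    rows = []
    for r, c in pixels:
        annotations = annotate_spectrum(
            dataset.mz, dataset.intensities[r, c], space, config
        )
        snr = {a.species.name: a.snr for a in annotations}
        for name in names:
            rows.append(
                {"row": r, "col": c, "species": name, "snr": snr.get(name, 0.0)}
            )
    return pd.DataFrame(rows)


@dataclass
class ProfileMatrix:
    """Patients × species matrix of median S/N with per-patient class labels."""

    values: pd.DataFrame  # index: patient id, columns: species names
    labels: pd.Series  # index: patient id, values: tissue class

    def __post_init__(self):
        if (self.values.to_numpy() < 0).any():
            raise ValueError("S/N values must be non-negative")
        if not self.values.index.equals(self.labels.index):
            raise ValueError("labels index must match the patient index")


def per_patient_median(
    snr_tables: Mapping[str, pd.DataFrame],
    patient_labels: Mapping[str, str],
) -> ProfileMatrix:
    """Collapse per-pixel S/N tables to a patients × species median matrix.

    ``snr_tables`` maps patient id → the long table produced by
    :func:`extract_region_snr`.  Species absent for a patient get 0.
    """
    if set(snr_tables) - set(patient_labels):
        raise ValueError("every patient needs a tissue-class label")
    medians = {
        patient: table.groupby("species")["snr"].median()
        for patient, table in snr_tables.items()
    }
    values = pd.DataFrame(medians).T.fillna(0.0).sort_index()
    labels = pd.Series({p: patient_labels[p] for p in values.index}, name="tissue_class")
    return ProfileMatrix(values=values, labels=labels)
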