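#!/usr/bin/env python
"""Annotate the simulated sections and summarize detection per region.

Reads the imzML sections written by 02_simulate_sections.py (under
scratch/sections/), runs the full annotation chain (noise estimation, peak
picking, 0.5-m/z charge-spacing inference, 5 ppm matching) on every pixel,
and writes per-region species summaries plus ion images of informative CL
species.

Writes results/sections/<name>/species_summary.tsv and ion_images.png.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from clmsi.annotate import AnnotationConfig
from clmsi.chem import LipidSpecies, default_species_space
from clmsi.imaging import RegionMask, extract_region_snr, ion_image, read_imzml

SECTIONS = Path(__file__).resolve().parents[1] / "scratch" / "sections"
RESULTS = Path(__file__).resolve().parents[1] / "results" / "sections"
ION_IMAGE_SPECIES = ("CL(72:8)", "CL(72:6)", "CL(74:8)", "CL(78:12)")


def main() -> None:
    config = AnnotationConfig()
    space = default_species_space()
    if not SECTIONS.exists():
        raise SystemExit("no simulated sections found; run 02_simulate_sections.py first")
    for section_dir in sorted(SECTIONS.iterdir()):
        if not (section_dir / "section.imzML").exists():
            continue
        out_dir = RESULTS / section_dir.name
        out_dir.mkdir(parents=True, exist_ok=True)
        dataset = read_imzml(section_dir / "section.imzML")
        mask = RegionMask.from_csv(
            section_dir / "mask.csv", section_dir / "mask_labels.json"
        )
        regions = sorted({l for l in mask.labels.ravel() if l != "unassigned"})
        summaries = []
        for region in regions:
            table = extract_region_snr(dataset, mask, region, space, config)
            summary = table.groupby("species")["snr"].median().rename("median_snr")
            summary = summary.reset_index()
            summary["region"] = region
            summary["detected"] = summary["median_snr"] >= config.snr_threshold
            summaries.append(summary)
        combined = pd.concat(summaries, ignore_index=True)
        combined.to_csv(out_dir / "species_summary.tsv", sep="\t", index=False)
        for region in regions:
            sub = combined[combined["region"] == region]
            n_cl = int(sub["detected"][sub["species"].str.startswith("CL(")].sum())
            n_mlcl = int(sub["detected"][sub["species"].str.startswith("MLCL(")].sum())
            print(f"{section_dir.name}/{region}: {n_cl} CL, {n_mlcl} MLCL detected")

        fig, axes = plt.subplots(1, len(ION_IMAGE_SPECIES), figsize=(13, 3.2))
        for ax, name in zip(axes, ION_IMAGE_SPECIES):
            lipid_class, xy = name.split("(")
            x, y = (int(v) for v in xy.rstrip(")").split(":"))
            target = LipidSpecies(lipid_class, x, y).mz_2minus
            image = ion_image(dataset, target, tol_ppm=config.tol_ppm)
            handle = ax.imshow(image.values, cmap="viridis")
            ax.set_title(f"{name}\nm/z {target:.3f}", fontsize=9)
            ax.set_xticks([]), ax.set_yticks([])
            fig.colorbar(handle, ax=ax, shrink=0.75)
        fig.suptitle(section_dir.name)
        fig.savefig(out_dir / "ion_images.png", dpi=120, bbox_inches="tight")
        plt.close(fig)


if __name__ == "__main__":
    main()
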