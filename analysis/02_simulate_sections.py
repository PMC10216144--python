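#!/usr/bin/env python
"""Simulate representative tissue sections and export them as imzML.

Three sections mirror the imaging scenarios of interest: a pure
normal-cortex section, a GBM section with pure plus infiltrating tumor
regions, and a GBM section with viable plus necrotic regions.  Each run
writes continuous-mode imzML, a region mask (CSV grid + JSON label map),
and ground-truth tables under scratch/sections/<name>/ (the imzML binary
payload is large; only derived summaries belong in results/).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from clmsi.imaging import RegionMask, write_imzml
from clmsi.synthetic import GeneratorConfig, generate_imaging_dataset

RESULTS = Path(__file__).resolve().parents[1] / "scratch" / "sections"
ROWS, COLS = 8, 8


def split_layout(left: str, right: str) -> tuple:
    return tuple(
        tuple(left if c < COLS // 2 else right for c in range(COLS))
        for _ in range(ROWS)
    )


SCENARIOS = {
    "normal_cortex": (None, 11),
    "gbm_with_infiltration": (split_layout("GBM", "infiltrating"), 12),
    "gbm_with_necrosis": (split_layout("GBM", "necrotic"), 13),
}


def main() -> None:
    for name, (layout, seed) in SCENARIOS.items():
        out = RESULTS / name
        out.mkdir(parents=True, exist_ok=True)
        config = GeneratorConfig(rows=ROWS, cols=COLS, layout=layout, seed=seed)
        dataset, truth = generate_imaging_dataset(config)
        write_imzml(dataset, out / "section.imzML")
        RegionMask(config.layout_array()).to_csv(
            out / "mask.csv", out / "mask_labels.json"
        )
        for key, table in truth.items():
            table.to_csv(out / f"truth_{key}.csv", index=False)
        regions = sorted(set(truth["pixels"]["label"]))
        print(f"{name}: {ROWS}x{COLS} section, regions {regions} -> {out}")


if __name__ == "__main__":
    main()
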