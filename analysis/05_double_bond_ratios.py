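#!/usr/bin/env python
"""Δ9/Δ11 double-bond isomer ratios from simulated CID/UVPD peak lists.

For each tissue class, simulates replicate UVPD diagnostic-ion peak lists
for the FA(18:1) chains of tri-oleoyl CL species with a class-specific
ground-truth Δ9:Δ11 ratio (elevated in grade-2 astrocytoma), recovers the
ratio with the diagnostic-ion statistic, and tests the groups pairwise.

Writes results/uvpd/{recovered_ratios.csv,group_tests.csv}.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import numpy as np
import pandas as pd

from clmsi.annotate import Centroid, dbond_ratio
from clmsi.profiling import group_compare
from clmsi.synthetic import generate_uvpd_peaklist

RESULTS = Path(__file__).resolve().parents[1] / "results" / "uvpd"

# Ground-truth Δ9:Δ11 ratios per tissue class: grade-2 astrocytoma carries
# relatively more Δ9 unsaturation than normal cortex or GBM.
TRUE_RATIOS = {"NL_grey": 2.0, "AST1": 2.3, "AST2": 3.2, "GBM": 2.0}
N_REPLICATES = 8
NOISE_CV = 0.10


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, (tissue, true_ratio) in enumerate(TRUE_RATIOS.items()):
        for replicate in range(N_REPLICATES):
            peaks = generate_uvpd_peaklist(
                true_ratio, noise_cv=NOISE_CV, seed=1000 * k + replicate
            )
            centroids = [
                Centroid(mz, intensity, j)
                for j, (mz, intensity) in enumerate(
                    zip(peaks["mz"], peaks["intensity"])
                )
            ]
            recovered = dbond_ratio(
                centroids, peaks["ions_delta9"], peaks["ions_delta11"]
            )
            rows.append(
                {"tissue_class": tissue, "replicate": replicate,
                 "true_ratio": true_ratio, "recovered_ratio": recovered}
            )
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "recovered_ratios.csv", index=False)
    summary = table.groupby("tissue_class")["recovered_ratio"].agg(["mean", "std"])
    print("recovered Δ9/Δ11 ratios (mean ± sd over replicates):")
    for tissue, true_ratio in TRUE_RATIOS.items():
        mean, sd = summary.loc[tissue, "mean"], summary.loc[tissue, "std"]
        print(f"  {tissue:8s} {mean:.2f} ± {sd:.2f}  (truth {true_ratio})")

    tests = group_compare(
        table["recovered_ratio"].to_numpy(), table["tissue_class"].to_numpy()
    )
    tests.to_csv(RESULTS / "group_tests.csv", index=False)
    ast2 = tests[
        (tests["group_a"] == "AST2") | (tests["group_b"] == "AST2")
    ]
    print(f"AST2 vs other classes ({tests['test'].iloc[0]}, Holm-adjusted): "
          f"max p_adj {ast2['p_adj'].max():.4f}")


if __name__ == "__main__":
    main()
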