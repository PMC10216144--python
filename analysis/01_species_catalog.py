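#!/usr/bin/env python
"""Enumerate the CL/MLCL composition space and tabulate exact masses.

Builds the default cardiolipin search space (68–80 acyl carbons, 2–14
double bonds, even totals) plus the monolysocardiolipin space, writes a
species catalog with neutral formulas and [M−2H]²⁻ exact m/z, and checks
the published identification table values against the formula rules.

Writes results/species_catalog.tsv and results/table1_check.csv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from clmsi.chem import (
    ElementalFormula,
    default_species_space,
    monoisotopic_mass,
    mz_doubly_deprotonated,
    ppm_error,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"

# Published identification table: (attribution, measured m/z, printed exact
# m/z, printed formula).  The MLCL rows and the CL(78:13) row carry printed
# formulas inconsistent with their own attributions (see docs/methods.md).
TABLE1 = [
    ("MLCL(52:2)", 582.379, 582.379, "C61H114O16P2"),
    ("MLCL(54:4)", 593.372, 593.371, "C63H112O16P2"),
    ("MLCL(56:5)", 606.380, 606.379, "C65H114O16P2"),
    ("MLCL(58:8)", 618.380, 618.379, "C67H114O16P2"),
    ("CL(70:5)", 712.487, 712.487, "C79H144O17P2"),
    ("CL(70:4)", 713.494, 713.495, "C79H146O17P2"),
    ("CL(72:8)", 723.480, 723.479, "C81H142O17P2"),
    ("CL(72:6)", 725.494, 725.495, "C81H146O17P2"),
    ("CL(72:4)", 727.509, 727.510, "C81H150O17P2"),
    ("CL(74:8)", 737.494, 737.495, "C83H146O17P2"),
    ("CL(74:7)", 738.502, 738.502, "C83H148O17P2"),
    ("CL(74:6)", 739.509, 739.510, "C83H150O17P2"),
    ("CL(76:10)", 749.494, 749.495, "C85H146O17P2"),
    ("CL(78:13)", 762.501, 762.502, "C87H148O17P2"),
]


def main() -> None:
    RESULTS.mkdir(exist_ok=True)

    space = default_species_space()
    catalog = pd.DataFrame(
        {
            "species": [s.name for s in space],
            "lipid_class": [s.lipid_class for s in space],
            "total_carbons": [s.total_carbons for s in space],
            "total_double_bonds": [s.total_double_bonds for s in space],
            "formula": [str(s.neutral_formula) for s in space],
            "neutral_mass": [round(s.neutral_mass, 5) for s in space],
            "mz_2minus": [round(s.mz_2minus, 5) for s in space],
        }
    )
    catalog.to_csv(RESULTS / "species_catalog.tsv", sep="\t", index=False)
    n_cl = (catalog["lipid_class"] == "CL").sum()
    print(f"species catalog: {n_cl} CL + {len(catalog) - n_cl} MLCL compositions "
          f"-> {RESULTS/'species_catalog.tsv'}")

    rows = []
    for attribution, measured, exact_printed, formula in TABLE1:
        lipid_class, xy = attribution.split("(")
        x, y = (int(v) for v in xy.rstrip(")").split(":"))
        from clmsi.chem import LipidSpecies

        species = LipidSpecies(lipid_class, x, y)
        mz_formula_route = mz_doubly_deprotonated(
            monoisotopic_mass(ElementalFormula.parse(formula))
        )
        rows.append(
            {
                "attribution": attribution,
                "printed_formula": formula,
                "printed_exact_mz": exact_printed,
                "mz_from_attribution": round(species.mz_2minus, 5),
                "mz_from_printed_formula": round(mz_formula_route, 5),
                "formula_from_attribution": str(species.neutral_formula),
                "attribution_consistent": abs(species.mz_2minus - exact_printed) < 6e-4,
                "ppm_measured_vs_formula_mz": round(
                    ppm_error(measured, mz_formula_route), 2
                ),
            }
        )
    check = pd.DataFrame(rows)
    check.to_csv(RESULTS / "table1_check.csv", index=False)
    n_consistent = int(check["attribution_consistent"].sum())
    print(f"identification-table check: {n_consistent}/{len(check)} rows have "
          "attribution (X:Y) consistent with their printed exact m/z")
    inconsistent = check.loc[~check["attribution_consistent"], "attribution"].tolist()
    if inconsistent:
        print(f"  inconsistent rows (printed formula disagrees with attribution): "
              f"{inconsistent}")
    cl = check[check["attribution"].str.startswith("CL")]
    print(f"  max |ppm| measured vs formula-computed m/z across CL rows: "
          f"{cl['ppm_measured_vs_formula_mz'].abs().max():.2f} (tolerance 5)")


if __name__ == "__main__":
    main()
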