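"""Chemistry core for cardiolipin (CL) imaging mass spectrometry.

Everything downstream — the synthetic-data generator, annotation, and the
statistics — rests on the small amount of chemistry in this module:

* elemental-formula arithmetic with monoisotopic masses,
* the CL / monolysocardiolipin (MLCL) sum-composition rules
  (``CL(X:Y)`` has neutral formula ``C(X+9) H(2X−2Y+14) O17 P2``,
  ``MLCL(X:Y)`` is CL minus one acyl residue: ``C(X+9) H(2X−2Y+16) O16 P2``),
* the doubly deprotonated ion m/z ``(M − 2·m_p)/2`` that dominates the
  negative-mode spectrum of these dianionic phospholipids,
* aggregated isotope envelopes (the 0.5-m/z isotopologue spacing at z = −2
  is the charge signature used to attribute CL peaks),
* fatty-acyl carboxylate anion m/z for tandem-MS chain assignment, and
* the 24-Da diagnostic fragment pairs that localize C=C double bonds in
  hybrid CID/UVPD spectra.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ATOMIC_MASS",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "C13_C12_SPACING",
    "ElementalFormula",
    "FattyAcyl",
    "LipidSpecies",
    "IsotopeEnvelope",
    "monoisotopic_mass",
    "mz_doubly_deprotonated",
    "cl_formula",
    "mlcl_formula",
    "ppm_error",
    "enumerate_cl_space",
    "default_species_space",
    "isotope_envelope",
    "fa_anion_mz",
    "fa_combinations",
    "diagnostic_pair_mz",
    "species_table",
]

# Monoisotopic atomic masses (Da); carbon-12 defines the scale.
ATOMIC_MASS: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "O": 15.9949146196,
    "P": 30.97376163,
    "N": 14.0030740048,
    "S": 31.97207100,
}

#: Mass of a proton (hydrogen atom minus one electron), Da.
PROTON_MASS = 1.00727646688
#: Electron mass, Da.
ELECTRON_MASS = 5.48579909e-4
#: m(13C) − m(12C); isotopologue spacing of a carbon-dominated envelope.
C13_C12_SPACING = 1.0033548

# Nominal-mass isotope distributions (offset in nucleons, fractional
# abundance).  Aggregated at unit resolution: at resolving power 70,000 the
# fine structure of M+1/M+2 is unresolved and only the spacing and gross
# abundances matter for charge inference.
_ISOTOPES: Mapping[str, tuple[tuple[int, float], ...]] = {
    "C": ((0, 0.9893), (1, 0.0107)),
    "H": ((0, 0.999885), (1, 0.000115)),
    "O": ((0, 0.99757), (1, 0.00038), (2, 0.00205)),
    "P": ((0, 1.0),),
    "N": ((0, 0.99636), (1, 0.00364)),
    "S": ((0, 0.9499), (1, 0.0075), (2, 0.0425), (4, 0.0001)),
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ElementalFormula:
    """Immutable element → count map with element-wise arithmetic.

    Counts are non-negative integers; subtraction that would drive any
    count negative raises ``ValueError``.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None, **kwargs: int):
        merged: dict[str, int] = {}
        for source in (counts or {}), kwargs:
            for element, n in source.items():
                if int(n) != n or n < 0:
                    raise ValueError(
                        f"count for element {element!r} must be a non-negative "
                        f"integer, got {n!r}"
                    )
                if n:
                    merged[element] = merged.get(element, 0) + int(n)
        self._counts = merged

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse a plain formula string such as ``"C81H150O17P2"``."""
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(text):
            if match.start() != pos:
                break
            element, digits = match.groups()
            counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
            pos = match.end()
        if pos != len(text) or not counts:
            raise ValueError(f"cannot parse elemental formula {text!r}")
        return cls(counts)

    def items(self):
        return self._counts.items()

    def __getitem__(self, element: str) -> int:
        return self._counts.get(element, 0)

    def __bool__(self) -> bool:
        return bool(self._counts)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self._counts)
        for element, n in other.items():
            counts[element] = counts.get(element, 0) + n
        return ElementalFormula(counts)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self._counts)
        for element, n in other.items():
            remaining = counts.get(element, 0) - n
            if remaining < 0:
                raise ValueError(
                    f"subtraction yields negative count for element {element!r}"
                )
            counts[element] = remaining
        return ElementalFormula(counts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ElementalFormula):
            return NotImplemented
        return self._counts == other._counts

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical.
        parts = []
        for element in ("C", "H"):
            n = self._counts.get(element, 0)
            if n:
                parts.append(f"{element}{n if n > 1 else ''}")
        for element in sorted(self._counts):
            if element in ("C", "H"):
                continue
            n = self._counts[element]
            parts.append(f"{element}{n if n > 1 else ''}")
        return "".join(parts) or "(empty)"

    def __repr__(self) -> str:
        return f"ElementalFormula({self})"


def monoisotopic_mass(formula: ElementalFormula) -> float:
    """Monoisotopic mass in Da: sum of count × tabulated atomic mass."""
    total = 0.0
    for element, n in formula.items():
        try:
            total += n * ATOMIC_MASS[element]
        except KeyError:
            raise ValueError(f"unknown element symbol {element!r}") from None
    return total


def mz_doubly_deprotonated(neutral_mass: float) -> float:
    """m/z of the [M − 2H]²⁻ ion of a neutral of the given monoisotopic mass."""
    mz = (neutral_mass - 2.0 * PROTON_MASS) / 2.0
    if mz < 0:
        raise ValueError(
            f"neutral mass {neutral_mass} is below the mass of two protons"
        )
    return mz


def cl_formula(total_carbons: int, total_double_bonds: int) -> ElementalFormula:
    """Neutral formula of cardiolipin CL(X:Y): C(X+9) H(2X−2Y+14) O17 P2.

    X counts acyl-chain carbons only (the 9 backbone carbons of the two
    glycerophosphate units and the bridging glycerol are added here); Y is
    the total number of acyl C=C double bonds.
    """
    x, y = int(total_carbons), int(total_double_bonds)
    if x < 8:
        raise ValueError(f"CL needs at least 8 acyl carbons (four chains), got {x}")
    if y < 0:
        raise ValueError(f"double-bond count must be non-negative, got {y}")
    h = 2 * x - 2 * y + 14
    if h <= 0:
        raise ValueError(f"CL({x}:{y}) would have non-positive hydrogen count {h}")
    return ElementalFormula(C=x + 9, H=h, O=17, P=2)


def mlcl_formula(total_carbons: int, total_double_bonds: int) -> ElementalFormula:
    """Neutral formula of monolysocardiolipin MLCL(X:Y): C(X+9) H(2X−2Y+16) O16 P2.

    Derived from the CL rule by ester hydrolysis of one acyl chain
    (remove the fatty acyl residue FA − H2O).
    """
    x, y = int(total_carbons), int(total_double_bonds)
    if x < 6:
        raise ValueError(f"MLCL needs at least 6 acyl carbons (three chains), got {x}")
    if y < 0:
        raise ValueError(f"double-bond count must be non-negative, got {y}")
    h = 2 * x - 2 * y + 16
    if h <= 0:
        raise ValueError(f"MLCL({x}:{y}) would have non-positive hydrogen count {h}")
    return ElementalFormula(C=x + 9, H=h, O=16, P=2)


_CLASS_FORMULA = {"CL": cl_formula, "MLCL": mlcl_formula}
_CLASS_CHAINS = {"CL": 4, "MLCL": 3}


def ppm_error(measured: float, exact: float) -> float:
    """Signed mass error in parts per million; positive when measured > exact."""
    if exact <= 0:
        raise ValueError(f"exact m/z must be positive, got {exact}")
    return 1e6 * (measured - exact) / exact


@dataclass(frozen=True)
class FattyAcyl:
    """A fatty acyl chain ``carbons:double_bonds``, optionally with localized
    double-bond positions (Δn, counted from the carboxyl carbon)."""

    carbons: int
    double_bonds: int
    db_positions: tuple[int, ...] | None = None

    def __post_init__(self):
        if self.carbons < 2:
            raise ValueError(f"fatty acyl needs at least 2 carbons, got {self.carbons}")
        if not 0 <= self.double_bonds <= (self.carbons - 2) // 2:
            raise ValueError(
                f"FA {self.carbons}:{self.double_bonds} exceeds the maximum "
                f"unsaturation for its chain length"
            )
        if self.db_positions is not None:
            positions = tuple(self.db_positions)
            object.__setattr__(self, "db_positions", positions)
            if len(positions) != self.double_bonds:
                raise ValueError("db_positions length must equal double_bonds")
            for p in positions:
                if not 2 <= p <= self.carbons - 2:
                    raise ValueError(f"double-bond position Δ{p} outside 2..C−2")

    @classmethod
    def parse(cls, text: str) -> "FattyAcyl":
        """Parse shorthand such as ``"18:1"``."""
        a, b = text.split(":")
        return cls(int(a), int(b))

    @property
    def name(self) -> str:
        return f"{self.carbons}:{self.double_bonds}"

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True)
class LipidSpecies:
    """A CL or MLCL sum composition: total acyl carbons X and double bonds Y."""

    lipid_class: str
    total_carbons: int
    total_double_bonds: int

    def __post_init__(self):
        if self.lipid_class not in _CLASS_FORMULA:
            raise ValueError(f"unknown lipid class {self.lipid_class!r}")
        _CLASS_FORMULA[self.lipid_class](self.total_carbons, self.total_double_bonds)

    @property
    def neutral_formula(self) -> ElementalFormula:
        return _CLASS_FORMULA[self.lipid_class](
            self.total_carbons, self.total_double_bonds
        )

    @property
    def neutral_mass(self) -> float:
        return monoisotopic_mass(self.neutral_formula)

    @property
    def mz_2minus(self) -> float:
        """Exact m/z of the doubly deprotonated ion [M − 2H]²⁻."""
        return mz_doubly_deprotonated(self.neutral_mass)

    @property
    def n_chains(self) -> int:
        return _CLASS_CHAINS[self.lipid_class]

    @property
    def name(self) -> str:
        return f"{self.lipid_class}({self.total_carbons}:{self.total_double_bonds})"

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True)
class IsotopeEnvelope:
    """First k isotopologue peaks of an ion at charge z, monoisotopic peak = 1."""

    mz: tuple[float, ...]
    abundance: tuple[float, ...]
    charge: int

    @property
    def spacing(self) -> float:
        return C13_C12_SPACING / abs(self.charge)

    def __len__(self) -> int:
        return len(self.mz)


@lru_cache(maxsize=4096)
def _aggregate_distribution(formula: ElementalFormula, k: int) -> tuple[float, ...]:
    """Nominal-mass isotopologue abundances by element-wise convolution."""
    dist = np.array([1.0])
    for element, n in formula.items():
        try:
            pattern = _ISOTOPES[element]
        except KeyError:
            raise ValueError(f"no isotope data for element {element!r}") from None
        elem = np.zeros(max(offset for offset, _ in pattern) + 1)
        for offset, abundance in pattern:
            elem[offset] = abundance
        for _ in range(n):
            dist = np.convolve(dist, elem)[:k]
    return tuple(dist[:k])


def isotope_envelope(
    formula: ElementalFormula, z: int, k: int = 6
) -> IsotopeEnvelope:
    """Aggregated isotope envelope of the deprotonated ion at charge z.

    Abundances come from convolving the natural isotope distributions of
    every atom, pooled at nominal (unit) mass; peaks are placed at
    ``mz_mono + j·1.0033548/|z|``, the spacing of a ¹³C-dominated envelope.
    Trailing all-zero peaks are dropped.
    """
    if z == 0:
        raise ValueError("charge must be non-zero")
    if k < 1:
        raise ValueError("at least one isotopologue peak is required")
    abundances = np.array(_aggregate_distribution(formula, k))
    if abundances[0] <= 0:
        raise ValueError("monoisotopic abundance is zero; cannot normalize")
    abundances = abundances / abundances[0]
    nonzero = np.nonzero(abundances > 1e-12)[0]
    abundances = abundances[: nonzero[-1] + 1]
    n_charges = abs(z)
    mono_mz = (monoisotopic_mass(formula) - n_charges * PROTON_MASS) / n_charges
    mz = mono_mz + np.arange(len(abundances)) * (C13_C12_SPACING / n_charges)
    return IsotopeEnvelope(tuple(mz), tuple(abundances), z)


def fa_anion_mz(fa: FattyAcyl) -> float:
    """m/z of the fatty-acid carboxylate anion [CaH(2a−2b−1)O2]⁻.

    These are the dominant CID fragments of deprotonated CL and carry the
    chain-composition information; the electron mass is included.
    """
    h = 2 * fa.carbons - 2 * fa.double_bonds - 1
    formula = ElementalFormula(C=fa.carbons, H=h, O=2)
    return monoisotopic_mass(formula) + ELECTRON_MASS


def fa_combinations(
    total_carbons: int,
    total_double_bonds: int,
    pool: Sequence[FattyAcyl],
    n_chains: int,
) -> list[tuple[FattyAcyl, ...]]:
    """All chain multisets of size ``n_chains`` from ``pool`` summing to (X, Y).

    Each multiset is returned in canonical order (descending carbons, then
    descending double bonds); the list itself is sorted the same way.
    """
    if not pool:
        raise ValueError("fatty acyl pool must be non-empty")
    if n_chains < 1:
        raise ValueError("n_chains must be at least 1")
    key = lambda fa: (-fa.carbons, -fa.double_bonds)
    unique_pool = sorted(set(pool), key=key)
    results = set()
    for combo in itertools.combinations_with_replacement(unique_pool, n_chains):
        if (
            sum(fa.carbons for fa in combo) == total_carbons
            and sum(fa.double_bonds for fa in combo) == total_double_bonds
        ):
            results.add(tuple(sorted(combo, key=key)))
    return sorted(results, key=lambda combo: [key(fa) for fa in combo])


def diagnostic_pair_mz(fa: FattyAcyl) -> tuple[float, float]:
    """m/z pair of the C–C cleavage fragments flanking a localized double bond.

    Hybrid CID/UVPD of a carboxylate anion with one C=C at Δn cleaves the
    C–C bonds on either side of the double bond, giving two
    carboxylate-retaining fragment ions that differ by exactly two carbon
    atoms (24.0000 Da).  Convention used here for the terminal-atom
    bookkeeping: the lighter fragment is the saturated carboxylate
    [C(n−1)H(2n−3)O2]⁻ truncated just before the double bond, and the
    heavier fragment adds the two (hydrogen-free) sp² carbons.  Any
    consistent hydrogen-transfer convention shifts both members of the pair
    together, so the 24-Da gap and the Δ9/Δ11 disjointness are unaffected.
    """
    if fa.double_bonds != 1 or not fa.db_positions:
        raise ValueError(
            "diagnostic pairs are defined only for chains with exactly one "
            "localized double bond"
        )
    (position,) = fa.db_positions
    light = (
        monoisotopic_mass(
            ElementalFormula(C=position - 1, H=2 * position - 3, O=2)
        )
        + ELECTRON_MASS
    )
    return (light, light + 2 * ATOMIC_MASS["C"])


def enumerate_cl_space(
    carbon_min: int,
    carbon_max: int,
    db_min: int,
    db_max: int,
    classes: Iterable[str] = ("CL",),
    carbon_step: int = 2,
    db_step: int = 1,
) -> list[LipidSpecies]:
    """Enumerate the CL/MLCL sum-composition space, sorted by [M−2H]²⁻ m/z.

    The default even-carbon step reflects the predominance of even-chain
    natural fatty acids; pass ``carbon_step=1`` to include odd totals.
    """
    species: set[LipidSpecies] = set()
    for lipid_class in classes:
        if lipid_class not in _CLASS_FORMULA:
            raise ValueError(f"unknown lipid class {lipid_class!r}")
        for x in range(carbon_min, carbon_max + 1, carbon_step):
            for y in range(db_min, db_max + 1, db_step):
                try:
                    species.add(LipidSpecies(lipid_class, x, y))
                except ValueError:
                    continue  # chemically impossible corner of the grid
    return sorted(species, key=lambda s: (s.mz_2minus, s.lipid_class))


#: Default composition-space bounds used throughout the pipeline.
DEFAULT_CL_RANGE = (68, 80, 2, 14)
DEFAULT_MLCL_RANGE = (50, 60, 1, 9)

#: Default fatty acyl pool for chain assignment; covers the chains reported
#: for the major brain CL species.
DEFAULT_FA_POOL = tuple(
    FattyAcyl.parse(s)
    for s in ("14:0", "16:0", "16:1", "18:0", "18:1", "18:2", "18:3", "20:3", "20:4", "22:6")
)


def default_species_space() -> list[LipidSpecies]:
    """CL plus MLCL default enumeration, one sorted list."""
    cl = enumerate_cl_space(*DEFAULT_CL_RANGE, classes=("CL",))
    mlcl = enumerate_cl_space(*DEFAULT_MLCL_RANGE, classes=("MLCL",))
    return sorted(cl + mlcl, key=lambda s: (s.mz_2minus, s.lipid_class))


def species_table(
    species: Sequence[LipidSpecies],
    measured_mz: Mapping[LipidSpecies, float] | None = None,
    fa_composition: Mapping[LipidSpecies, str] | None = None,
) -> pd.DataFrame:
    """Tabulate species the way annotation tables are reported.

    Columns: measured m/z (optional), attribution, FA composition, exact
    m/z, mass error (ppm), and proposed neutral formula.
    """
    measured_mz = measured_mz or {}
    fa_composition = fa_composition or {}
    rows = []
    for sp in species:
        exact = sp.mz_2minus
        measured = measured_mz.get(sp)
        rows.append(
            {
                "measured_mz": round(measured, 3) if measured is not None else None,
                "attribution": f"[{sp.name}-2H]2-",
                "fa_composition": fa_composition.get(sp, ""),
                "exact_mz": round(exact, 3),
                "ppm": round(abs(ppm_error(measured, exact)), 1)
                if measured is not None
                else None,
                "formula": str(sp.neutral_formula),
            }
        )
    return pd.DataFrame(rows)
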