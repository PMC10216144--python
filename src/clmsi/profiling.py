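"""Statistical readouts over per-patient CL profile matrices.

Three readouts summarize how cardiolipin remodeling shifts with pathology:

* the chain-length ratio S/N(CL 78:12) / S/N(CL 72:8), a scalar marker of
  mature (long, polyunsaturated) versus immature (short, saturated) CL —
  high in normal cortex (≈0.48) and collapsing toward 0 in glioblastoma;
* PCA of the log-transformed, column-centered median-S/N matrix, with
  per-species contribution percentages to each component;
* nonparametric (or, when every group passes a Shapiro–Wilk normality
  gate, parametric) pairwise group comparisons with Holm step-down
  adjustment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .imaging import ProfileMatrix

__all__ = [
    "DEFAULT_LONG_SPECIES",
    "DEFAULT_SHORT_SPECIES",
    "PcaResult",
    "chain_ratio",
    "log_center_pca",
    "group_compare",
    "species_richness",
]

DEFAULT_LONG_SPECIES = "CL(78:12)"
DEFAULT_SHORT_SPECIES = "CL(72:8)"


def chain_ratio(
    matrix: ProfileMatrix | pd.DataFrame,
    long_species: str = DEFAULT_LONG_SPECIES,
    short_species: str = DEFAULT_SHORT_SPECIES,
) -> tuple[pd.Series, int]:
    """Per-patient long/short chain S/N ratio.

    Returns the ratio series and the number of patients excluded because
    the denominator S/N was 0 (the ratio is undefined there, not 0).
    """
    values = matrix.values if isinstance(matrix, ProfileMatrix) else matrix
    for column in (long_species, short_species):
        if column not in values.columns:
            raise ValueError(f"species column {column!r} missing from the matrix")
    denominator = values[short_species]
    defined = denominator > 0
    ratios = values.loc[defined, long_species] / denominator[defined]
    ratios.name = f"{long_species}/{short_species}"
    return ratios, int((~defined).sum())


@dataclass
class PcaResult:
    """Scores, loadings, explained-variance fractions and contribution %."""

    scores: pd.DataFrame  # patients × components
    loadings: pd.DataFrame  # species × components
    explained_variance_ratio: np.ndarray
    contributions: pd.DataFrame  # species × components, percent, sums to 100


def log_center_pca(
    matrix: ProfileMatrix | pd.DataFrame,
    n_components: int = 2,
    pseudocount: float = 1.0,
) -> PcaResult:
    """PCA of ``log10(S/N + pseudocount)`` after column centering.

    No unit-variance scaling is applied — the analysis is of the centered
    log-S/N covariance.  The contribution of species *s* to component *c*
    is ``100 · loading²(s, c) / Σ_s loading²(s, c)``.  The pseudocount (1
    by default) keeps zero-S/N entries finite.
    """
    values = matrix.values if isinstance(matrix, ProfileMatrix) else matrix
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("PCA needs at least 2 patients and 2 species")
    log_values = np.log10(values.to_numpy(dtype=float) + pseudocount)
    if np.allclose(log_values.var(axis=0).sum(), 0.0):
        raise ValueError("matrix has no variance; PCA is undefined")
    n_components = min(n_components, min(values.shape) - 0)
    pca = PCA(n_components=n_components)  # centers columns internally
    scores = pca.fit_transform(log_values)
    components = ["PC%d" % (i + 1) for i in range(pca.n_components_)]
    loadings = pd.DataFrame(
        pca.components_.T, index=values.columns, columns=components
    )
    squared = loadings**2
    contributions = 100.0 * squared / squared.sum(axis=0)
    return PcaResult(
        scores=pd.DataFrame(scores, index=values.index, columns=components),
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_,
        contributions=contributions,
    )


def group_compare(
    values: pd.Series | np.ndarray,
    labels: pd.Series | np.ndarray,
    paired: bool = False,
    normality_alpha: float = 0.05,
) -> pd.DataFrame:
    """All pairwise group comparisons with a normality gate and Holm adjustment.

    Every group is Shapiro–Wilk tested at ``normality_alpha``; if all
    groups look normal, two-sample *t*-tests are used (paired on request),
    otherwise Wilcoxon rank-sum (Mann–Whitney) tests, or signed-rank when
    paired.  Raw p-values across all pairs receive Holm step-down
    adjustment, so adjusted p ≥ raw p always.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = {}
    for label in pd.unique(labels):
        group = values[labels == label]
        if len(group) < 3:
            raise ValueError(
                f"group {label!r} has only {len(group)} values; at least 3 required"
            )
        groups[label] = group
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    def looks_normal(group: np.ndarray) -> bool:
        if np.ptp(group) == 0:
            return False  # degenerate group; Shapiro–Wilk is undefined
        return sps.shapiro(group).pvalue > normality_alpha

    all_normal = all(looks_normal(g) for g in groups.values())
    rows = []
    for a, b in itertools.combinations(groups, 2):
        ga, gb = groups[a], groups[b]
        if all_normal:
            test = "paired t" if paired else "t"
            result = sps.ttest_rel(ga, gb) if paired else sps.ttest_ind(ga, gb)
        elif paired:
            test = "wilcoxon signed-rank"
            result = sps.wilcoxon(ga, gb)
        else:
            test = "wilcoxon rank-sum"
            result = sps.mannwhitneyu(ga, gb, alternative="two-sided")
        rows.append(
            {"group_a": a, "group_b": b, "test": test, "p_raw": float(result.pvalue)}
        )
    table = pd.DataFrame(rows)
    table["p_adj"] = multipletests(table["p_raw"], method="holm")[1]
    # Holm guarantees this, but it is the contract downstream code relies on.
    table["p_adj"] = np.maximum(table["p_adj"], table["p_raw"])
    return table


def species_richness(
    matrix: ProfileMatrix | pd.DataFrame,
    threshold: float = 3.0,
    lipid_class: str | None = None,
) -> pd.Series:
    """Detected-species count per patient: columns with S/N ≥ threshold.

    ``lipid_class`` restricts the count to species whose column name starts
    with that class prefix (e.g. ``"CL"`` excludes MLCL columns).
    """
    values = matrix.values if isinstance(matrix, ProfileMatrix) else matrix
    if lipid_class is not None:
        columns = [c for c in values.columns if c.startswith(f"{lipid_class}(")]
        values = values[columns]
    counts = (values >= threshold).sum(axis=1)
    counts.name = "n_detected"
    return counts
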