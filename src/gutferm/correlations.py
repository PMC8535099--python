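"""Taxa-metabolite association: Spearman matrix and two-way ordering.

Taxa (qPCR, triplicate) and VOCs (GC-MS, duplicate) have different
technical replication, so pairing is at condition level: technical
replicas are averaged within each (treatment, time, experiment) and the
resulting condition means are correlated.  Significance is by
average-rank Spearman correlation — exact permutation p for fewer than
10 pairs, t approximation otherwise.  For heatmap output, rows and
columns are ordered by complete-linkage clustering of the correlation
profiles under a 1 - Pearson distance, with lexicographic label order
as the deterministic tie-break.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import ValidationError
from .io import TaxonAbundanceTable, VocTable

EXACT_P_MAX_N = 9  # exact permutation p up to this many pairs


@dataclass
class CorrelationMatrix:
    rho: pd.DataFrame                 # taxa x compounds
    p: pd.DataFrame
    n: pd.DataFrame                   # pairs used per cell
    row_order: list[str] | None = None
    col_order: list[str] | None = None
    row_linkage: np.ndarray | None = None
    col_linkage: np.ndarray | None = None

    def ordered(self) -> pd.DataFrame:
        if self.row_order is None or self.col_order is None:
            raise ValidationError("call cluster_order() first")
        return self.rho.loc[self.row_order, self.col_order]


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Average-rank Spearman correlation (Pearson on midranks)."""
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


@lru_cache(maxsize=4)
def _perm_indices(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def spearman_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided p for a Spearman rho.

    Exact over all n! pairings for n <= 9 (ties handled via midranks);
    the usual t approximation otherwise.
    """
    n = len(x)
    if not np.isfinite(rho):
        return float("nan")
    if n <= EXACT_P_MAX_N:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        ry_perm = ry[_perm_indices(n)]  # every pairing of y's ranks with x
        rx_c = rx - rx.mean()
        ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
        denom = np.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum(axis=1))
        rhos = (ry_c @ rx_c) / denom
        return float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    t = rho * np.sqrt((n - 2) / max(1e-300, 1.0 - rho ** 2))
    return float(2 * stats.t.sf(abs(t), df=n - 2))


def _condition_means(df: pd.DataFrame, label_col: str,
                     value_col: str) -> pd.DataFrame:
    g = df.groupby([label_col, "treatment", "time_h", "experiment"])
    return g[value_col].mean().reset_index()


def spearman_matrix(taxa: TaxonAbundanceTable, vocs: VocTable,
                    min_pairs: int = 4) -> CorrelationMatrix:
    """Spearman rho and p between every taxon and every compound.

    Technical replicas are averaged first; pairing is on
    (treatment, time, experiment).  Cells with fewer than ``min_pairs``
    paired points, or with a constant series, are reported missing (NaN),
    never as 0.
    """
    tm = _condition_means(taxa.data, "taxon", "log10_gcn")
    vd = vocs.data.copy()
    vd.loc[~vd["detected"], "value"] = 0.0
    vm = _condition_means(vd, "compound", "value")
    taxa_labels = sorted(tm["taxon"].unique())
    comp_labels = sorted(vm["compound"].unique())
    key = ["treatment", "time_h", "experiment"]
    rho = pd.DataFrame(np.nan, index=taxa_labels, columns=comp_labels)
    p = rho.copy()
    n = pd.DataFrame(0, index=taxa_labels, columns=comp_labels)
    t_wide = tm.pivot_table(index=key, columns="taxon", values="log10_gcn")
    v_wide = vm.pivot_table(index=key, columns="compound", values="value")
    joined = t_wide.join(v_wide, how="inner")
    for taxon in taxa_labels:
        for comp in comp_labels:
            pair = joined[[taxon, comp]].dropna()
            n.loc[taxon, comp] = len(pair)
            if len(pair) < min_pairs:
                continue
            r = spearman_rho(pair[taxon].to_numpy(), pair[comp].to_numpy())
            rho.loc[taxon, comp] = r
            p.loc[taxon, comp] = spearman_p(pair[taxon].to_numpy(),
                                            pair[comp].to_numpy(), r)
    return CorrelationMatrix(rho=rho, p=p, n=n)


# -- two-way ordering ------------------------------------------------------

def _pearson_distance(profiles: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distance between profile rows."""
    with np.errstate(invalid="ignore"):
        c = np.corrcoef(profiles)
    c = np.nan_to_num(c, nan=0.0)  # constant profiles: treat as uncorrelated
    d = 1.0 - c
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    return squareform(d, checks=False)


def _linkage_order(profiles: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    labels = sorted(profiles.index)  # lexicographic => deterministic ties
    z = hierarchy.linkage(_pearson_distance(profiles.loc[labels].to_numpy()),
                          method="complete")
    order = [labels[i] for i in hierarchy.leaves_list(z)]
    return order, z


def cluster_order(matrix: CorrelationMatrix,
                  ) -> tuple[list[str], list[str]]:
    """Order rows and columns by complete-linkage Pearson clustering.

    Row profiles are a taxon's rho over all compounds and vice versa.
    Missing rho values are imputed as 0 (no association) with a warning.
    The leaf order and linkage records are stored on the matrix.
    """
    if matrix.rho.shape[0] < 2 or matrix.rho.shape[1] < 2:
        raise ValidationError("clustering needs >= 2 rows and >= 2 columns")
    rho = matrix.rho
    if rho.isna().any().any():
        warnings.warn("missing correlations imputed as 0 for clustering",
                      stacklevel=2)
        rho = rho.fillna(0.0)
    matrix.row_order, matrix.row_linkage = _linkage_order(rho)
    matrix.col_order, matrix.col_linkage = _linkage_order(rho.T)
    return matrix.row_order, matrix.col_order


def plot_heatmap(matrix: CorrelationMatrix, path: str | Path,
                 alpha: float = 0.05) -> None:
    """Render the ordered correlation matrix with significance stars."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if matrix.row_order is None:
        cluster_order(matrix)
    rho = matrix.ordered()
    pvals = matrix.p.loc[matrix.row_order, matrix.col_order]
    fig, ax = plt.subplots(
        figsize=(max(6, 0.5 * rho.shape[1]), max(4, 0.4 * rho.shape[0])))
    im = ax.imshow(rho.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1,
                   aspect="auto")
    ax.set_xticks(range(rho.shape[1]), rho.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(rho.shape[0]), rho.index, fontsize=7)
    for i in range(rho.shape[0]):
        for j in range(rho.shape[1]):
            if pvals.iat[i, j] < alpha:
                ax.text(j, i, "*", ha="center", va="center", fontsize=7)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
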