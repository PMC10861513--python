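"""Per-gene distance-matrix correlation and cluster AUC ranking.

For each gene a between-variety Euclidean distance matrix is built on the
same day axes as the global matrix (for a single gene the distance
reduces to an absolute difference), flattened, and Pearson-correlated
with the flattened global matrix.  Because Pearson correlation is
location- and scale-invariant, no explicit matrix normalisation is
needed.  Per SOM cluster, the proportion of member genes whose
correlation exceeds each threshold on a uniform grid over [-1, 1] forms a
survival curve; its trapezoidal area, normalised by the range width so
the maximum is 1, ranks how characteristic the cluster is of the global
transcriptome trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import DistanceMatrix
from .expression import TimePointProfile
from .som import ClusterAssignment


@dataclass
class ClusterCurve:
    cluster: int
    thresholds: np.ndarray
    proportions: np.ndarray
    auc: float
    n_genes: int


def per_gene_distance(
    profile_row: TimePointProfile,
    profile_col: TimePointProfile,
    gene: str,
) -> pd.DataFrame:
    """Single-gene between-variety distance matrix.

    Entry (i, j) is |expr_row(gene, day_i) - expr_col(gene, day_j)| — the
    Euclidean distance of one-dimensional vectors — on the same day axes
    as the global matrix.
    """
    for prof, side in ((profile_row, "row"), (profile_col, "col")):
        if gene not in prof.values.index:
            raise KeyError(f"gene {gene!r} missing from {side} profile")
    r = profile_row.values.loc[gene].to_numpy(dtype=float)
    c = profile_col.values.loc[gene].to_numpy(dtype=float)
    return pd.DataFrame(
        np.abs(r[:, None] - c[None, :]),
        index=profile_row.days,
        columns=profile_col.days,
    )


def gene_global_correlation(
    gene_matrix: pd.DataFrame | np.ndarray,
    global_matrix: pd.DataFrame | np.ndarray,
) -> tuple[float, bool]:
    """Pearson r between the flattened gene and global matrices.

    Returns ``(r, defined)``; ``defined`` is False (and r is NaN) when
    either flattened vector has zero variance.
    """
    g = np.asarray(gene_matrix, dtype=float).ravel()
    G = np.asarray(global_matrix, dtype=float).ravel()
    if g.shape != G.shape:
        raise ValueError(f"shape mismatch: {g.shape} vs {G.shape}")
    if g.std() <= 0 or G.std() <= 0:
        return float("nan"), False
    return float(np.corrcoef(g, G)[0, 1]), True


def gene_correlation_table(
    profile_row: TimePointProfile,
    profile_col: TimePointProfile,
    global_d: DistanceMatrix,
    genes: list[str],
) -> pd.DataFrame:
    """Vectorised per-gene distance-matrix correlations for many genes.

    Returns a DataFrame indexed by gene with columns ``r`` and
    ``defined``.
    """
    R = profile_row.values.loc[genes].to_numpy(dtype=float)  # (n, T_r)
    C = profile_col.values.loc[genes].to_numpy(dtype=float)  # (n, T_c)
    M = np.abs(R[:, :, None] - C[:, None, :])  # (n, T_r, T_c)
    flat = M.reshape(len(genes), -1)
    G = global_d.values.to_numpy(dtype=float).ravel()
    g_sd = G.std()
    f_mean = flat.mean(axis=1, keepdims=True)
    f_sd = flat.std(axis=1)
    defined = (f_sd > 0) & (g_sd > 0)
    r = np.full(len(genes), np.nan)
    if g_sd > 0:
        cov = ((flat - f_mean) * (G - G.mean())).mean(axis=1)
        np.divide(cov, f_sd * g_sd, out=r, where=defined)
    return pd.DataFrame({"r": r, "defined": defined}, index=pd.Index(genes, name="gene"))


def cluster_threshold_curve(
    records: pd.DataFrame,
    assignment: ClusterAssignment,
    n_thresholds: int = 201,
    form: str = "above",
) -> list[ClusterCurve]:
    """Per-cluster threshold-survival curves of gene correlations.

    ``records`` is the output of :func:`gene_correlation_table`.  With
    ``form="above"`` (default) the curve at threshold t is the fraction
    of the cluster's defined-r genes with r >= t, which is non-increasing
    in t; ``form="below"`` gives the complementary cumulative form.
    Clusters with no defined-r genes are omitted.  The AUC is the
    trapezoidal integral divided by the threshold range width (2), so a
    cluster of perfectly correlated genes scores 1.
    """
    if n_thresholds < 2:
        raise ValueError("n_thresholds must be >= 2")
    if form not in ("above", "below"):
        raise ValueError(f"form must be 'above' or 'below', got {form!r}")
    thresholds = np.linspace(-1.0, 1.0, n_thresholds)
    curves: list[ClusterCurve] = []
    defined = records[records["defined"]]
    for unit in range(assignment.n_units):
        members = assignment.gene_unit[assignment.gene_unit == unit].index
        rs = defined.loc[defined.index.intersection(members), "r"].to_numpy()
        if rs.size == 0:
            continue
        if form == "above":
            props = (rs[None, :] >= thresholds[:, None]).mean(axis=1)
        else:
            props = (rs[None, :] <= thresholds[:, None]).mean(axis=1)
        auc = float(np.trapezoid(props, thresholds) / 2.0)
        curves.append(
            ClusterCurve(
                cluster=unit,
                thresholds=thresholds,
                proportions=props,
                auc=auc,
                n_genes=int(rs.size),
            )
        )
    return curves


def rank_clusters_by_auc(curves: list[ClusterCurve], k: int = 3) -> list[int]:
    """The k clusters with the largest AUC, ties towards the lower index."""
    if k < 1:
        raise ValueError("k must be >= 1")
    order = sorted(curves, key=lambda c: (-c.auc, c.cluster))
    return [c.cluster for c in order[:k]]
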