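"""Phenomic matrix analysis: scaling, SVD-PCA, hierarchical clustering.

The multi-assay endpoint battery is aggregated into a matrix with one row
per behavioral endpoint and one column per fish group (species). Following
the ClustVis workflow, rows are unit-variance scaled so every endpoint
contributes equally; principal components are obtained by singular value
decomposition with the groups as observations, and both axes are clustered
agglomeratively. The column dendrogram ("phenogram") is exported as a Newick
tree so it can be compared directly with the gene tree.
"""

from __future__ import annotations

import io
import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform


def build_endpoint_matrix(tidy: pd.DataFrame, value: str = "value",
                          endpoint: str = "endpoint", group: str = "group",
                          aggregate: str = "mean") -> pd.DataFrame:
    """Aggregate a tidy endpoint table to an endpoints x groups matrix.

    Default aggregation is the group mean of each endpoint over sessions;
    ``aggregate='none'`` keeps individual sessions as columns (exploratory
    per-fish mode, columns named group/session).
    """
    if aggregate == "mean":
        mat = tidy.pivot_table(index=endpoint, columns=group, values=value,
                               aggfunc="mean")
    elif aggregate == "none":
        t = tidy.copy()
        t["_col"] = t[group].astype(str) + "/" + t["session_id"].astype(str)
        mat = t.pivot_table(index=endpoint, columns="_col", values=value,
                            aggfunc="mean")
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    if mat.isna().any().any():
        raise ValueError("missing cells after aggregation: "
                         f"{mat.columns[mat.isna().any()].tolist()}")
    return mat


def scale_rows_unit_variance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center each row to mean 0 and scale to sample SD 1.

    Constant rows carry no contrast between groups; they are dropped with a
    warning. Requires at least two columns.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 columns to scale rows")
    X = matrix.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    constant = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    if constant.any():
        warnings.warn(f"dropping {int(constant.sum())} constant row(s): "
                      f"{matrix.index[constant].tolist()}")
    Z = (X[~constant] - mu[~constant]) / sd[~constant]
    return pd.DataFrame(Z, index=matrix.index[~constant], columns=matrix.columns)


def pca_svd(matrix: pd.DataFrame) -> dict:
    """PCA of the scaled matrix by SVD, with groups (columns) as observations.

    The observation matrix is the transpose (groups x endpoints); rows of the
    input are already centered across groups by the unit-variance scaling, so
    the SVD acts on a column-centered observation matrix. Returns component
    scores per group, endpoint loadings, and percent variance explained
    (sums to 100).
    """
    X = matrix.to_numpy(dtype=float).T      # observations x variables
    if not np.any(X):
        raise ValueError("degenerate all-zero matrix")
    X = X - X.mean(axis=0, keepdims=True)   # no-op after row scaling
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    n_comp = int(np.sum(s > s.max() * 1e-12))
    scores = U[:, :n_comp] * s[:n_comp]
    var = s[:n_comp] ** 2
    var_pct = 100.0 * var / (s ** 2).sum()
    comp = [f"PC{i + 1}" for i in range(n_comp)]
    return {
        "scores": pd.DataFrame(scores, index=matrix.columns, columns=comp),
        "loadings": pd.DataFrame(Vt[:n_comp].T, index=matrix.index, columns=comp),
        "variance_explained_pct": pd.Series(var_pct, index=comp),
        "singular_values": s[:n_comp],
    }


def _distance(X: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        return pdist(X, metric="euclidean")
    if metric == "correlation":
        return pdist(X, metric="correlation")
    raise ValueError(f"unknown distance {metric!r}")


def hcluster(matrix: pd.DataFrame, axis: str = "columns",
             distance: str = "correlation", linkage: str = "average") -> dict:
    """Agglomerative clustering of matrix rows or columns.

    Returns the scipy linkage matrix, the item labels in input order, and the
    dendrogram serialized as Newick (branch length = difference between the
    parent's and the child's merge heights). Cluster memberships at any cut
    are available via :func:`cut_clusters`.
    """
    if linkage not in ("average", "complete", "ward"):
        raise ValueError(f"unknown linkage {linkage!r}")
    X = matrix.to_numpy(dtype=float)
    labels = list(matrix.index)
    if axis == "columns":
        X = X.T
        labels = list(matrix.columns)
    if len(labels) == 1:
        return {"linkage": None, "labels": labels,
                "newick": f"{labels[0]}:0;"}
    d = _distance(X, distance)
    Z = hierarchy.linkage(d, method=linkage)
    return {"linkage": Z, "labels": labels,
            "newick": linkage_to_newick(Z, labels)}


def cut_clusters(clust: dict, n_clusters: int) -> dict:
    """Flat cluster labels from a hcluster result at a given cluster count."""
    if clust["linkage"] is None:
        return {clust["labels"][0]: 1}
    flat = hierarchy.fcluster(clust["linkage"], t=n_clusters, criterion="maxclust")
    return dict(zip(clust["labels"], (int(c) for c in flat)))


def linkage_to_newick(Z: np.ndarray, labels: list) -> str:
    """Serialize a scipy linkage matrix as a Newick string.

    Each leaf's branch length is the height of its first merge minus zero;
    each internal node's is the parent height minus its own height, so
    root-to-leaf path length equals the root merge height for every leaf
    (ultrametric dendrogram).
    """
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    children = {}
    for idx, (a, b, h, _) in enumerate(Z):
        node = n + idx
        heights[node] = float(h)
        children[node] = (int(a), int(b))

    def rec(node, parent_h):
        bl = parent_h - heights[node]
        if node < n:
            return f"{labels[node]}:{bl:.10g}"
        a, b = children[node]
        h = heights[node]
        return f"({rec(a, h)},{rec(b, h)}):{bl:.10g}"

    root = n + len(Z) - 1
    h = heights[root]
    a, b = children[root]
    return f"({rec(a, h)},{rec(b, h)});"


def heatmap_figure(scaled: pd.DataFrame, row_clust: dict, col_clust: dict,
                   path=None):
    """Clustered heatmap (reporting convenience; numbers are tested upstream)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    row_order = (hierarchy.leaves_list(row_clust["linkage"])
                 if row_clust["linkage"] is not None else range(len(scaled)))
    col_order = (hierarchy.leaves_list(col_clust["linkage"])
                 if col_clust["linkage"] is not None
                 else range(scaled.shape[1]))
    M = scaled.iloc[row_order, col_order]
    fig, ax = plt.subplots(figsize=(1.2 * M.shape[1] + 3, 0.25 * M.shape[0] + 2))
    im = ax.imshow(M.to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(M.shape[1]), M.columns, rotation=45, ha="right")
    ax.set_yticks(range(M.shape[0]), M.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="row z-score")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
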