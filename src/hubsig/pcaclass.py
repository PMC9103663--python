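"""PCA of the cancer-type x gene normalized-connections matrix.

Rows are cancer types (annotated with their aggressiveness class), columns
the variance-filtered genes, cells the per-type normalized connections.
Components come from the singular value decomposition of the column-centered
matrix (scaling off by default), matching the usual R ``prcomp`` semantics:
component standard deviations are singular values divided by sqrt(n_rows - 1)
and variance proportions are squared-singular-value shares. A gene's
contribution to a component is its squared-loading share of that component
(in percent); weighting contributions by the component variance proportions
gives the gene's share of total variance, and dividing by the cumulative
proportion of the retained components gives its share of captured variance.
Hierarchical clustering of the same rows (manhattan distance, complete
linkage by default) checks whether the two top-level branches separate the
H from the L types.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "FeatureMatrix",
    "PCAResult",
    "ClusterTree",
    "build_feature_matrix",
    "run_pca",
    "gene_contributions",
    "hierarchical_cluster",
]


@dataclass
class FeatureMatrix:
    """Dense cancer-type x gene matrix of normalized connections."""

    values: pd.DataFrame  # rows: cancer types; columns: genes
    row_classes: pd.Series  # cancer type -> "H"/"L"

    def __post_init__(self):
        missing = self.values.index.difference(self.row_classes.index)
        if len(missing):
            raise ValueError(f"no class annotation for rows {list(missing)}")
        self.row_classes = self.row_classes.reindex(self.values.index)


@dataclass
class PCAResult:
    sdev: np.ndarray  # per-component standard deviation
    proportions: np.ndarray  # variance proportions (sum to 1)
    cumulative: np.ndarray
    loadings: pd.DataFrame  # gene x component
    coords: pd.DataFrame  # row x component
    row_classes: pd.Series
    degenerate: bool = False  # constant matrix: no variance to decompose


@dataclass
class ClusterTree:
    linkage: np.ndarray
    labels: list[str]
    row_classes: pd.Series
    purity: float  # class purity of the 2-branch cut

    @property
    def separates_classes(self) -> bool:
        return self.purity == 1.0

    def two_branch_assignments(self) -> pd.Series:
        flat = hierarchy.fcluster(self.linkage, t=2, criterion="maxclust")
        return pd.Series(flat, index=self.labels)

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with merge-height branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{parent_height - 0.0:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{max(length, 0.0):.6g}"

        body = (
            f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)})"
            if not tree.is_leaf()
            else self.labels[tree.id]
        )
        return body + ";"


def build_feature_matrix(
    stats: pd.DataFrame, genes: set[str] | list[str],
    row_classes: pd.Series | dict[str, str],
) -> FeatureMatrix:
    """Pivot per-cancer-type gene statistics into the PCA input matrix.

    ``stats`` is a tidy table grouped by cancer type with norm_connections;
    absences become zero cells. Column order follows the sorted gene list.
    """
    genes = sorted(genes)
    if not genes:
        raise ValueError("empty gene selection")
    sub = stats[stats["gene"].isin(genes)]
    wide = (
        sub.pivot(index="group", columns="gene", values="norm_connections")
        .reindex(columns=genes)
        .fillna(0.0)
    )
    wide.index.name = "cancer_type"
    return FeatureMatrix(values=wide, row_classes=pd.Series(dict(row_classes)))


def run_pca(
    matrix: FeatureMatrix, center: bool = True, scale: bool = False
) -> PCAResult:
    """Principal components of the feature matrix via SVD.

    At most min(n_rows - 1, n_cols) components are kept (centering removes
    one rank). Loadings are sign-fixed so each component's largest-magnitude
    loading is positive. A constant matrix (zero total variance) is returned
    flagged rather than raising.
    """
    X = matrix.values.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    if center:
        X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    k = min(n - 1, p) if center else min(n, p)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    total = float(np.sum(S**2))
    if total == 0.0:
        props = np.zeros(k)
        degenerate = True
    else:
        props = S**2 / total
        degenerate = False
    # reproducible sign convention
    for j in range(k):
        i_max = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    comp_names = [f"PC{j + 1}" for j in range(k)]
    sdev = S / np.sqrt(n - 1)
    loadings = pd.DataFrame(Vt.T, index=matrix.values.columns, columns=comp_names)
    coords = pd.DataFrame(U * S, index=matrix.values.index, columns=comp_names)
    return PCAResult(
        sdev=sdev,
        proportions=props,
        cumulative=np.cumsum(props),
        loadings=loadings,
        coords=coords,
        row_classes=matrix.row_classes,
        degenerate=degenerate,
    )


def gene_contributions(result: PCAResult, retained: int = 3) -> pd.DataFrame:
    """Per-gene contribution percentages and variance shares.

    contribution(g, k) = 100 x loading(g, k)^2 / sum_g loading(g, k)^2.
    ``total_share`` weights contributions by the components' variance
    proportions (over all components); ``captured_share`` renormalizes the
    retained-component part by the cumulative proportion they capture.
    """
    if retained < 1:
        raise ValueError("retained must be >= 1")
    k = result.loadings.shape[1]
    if retained > k:
        raise ValueError(f"retained={retained} exceeds {k} available components")
    sq = result.loadings.to_numpy() ** 2
    col_sums = sq.sum(axis=0)
    col_sums[col_sums == 0] = 1.0
    contrib = 100.0 * sq / col_sums
    table = pd.DataFrame(
        contrib, index=result.loadings.index, columns=result.loadings.columns
    )
    total_share = contrib @ result.proportions
    retained_share = contrib[:, :retained] @ result.proportions[:retained]
    cum = result.cumulative[retained - 1]
    table["total_share"] = total_share
    table["captured_share"] = retained_share / cum if cum > 0 else float("nan")
    return table


def hierarchical_cluster(
    matrix: FeatureMatrix,
    on: str = "matrix",
    result: PCAResult | None = None,
    retained: int = 3,
    metric: str = "cityblock",
    linkage_method: str = "complete",
) -> ClusterTree:
    """Agglomerative clustering of cancer types; manhattan distance default.

    ``on="matrix"`` clusters the raw feature rows; ``on="pcs"`` clusters the
    first ``retained`` PC coordinates of a supplied PCA result. The reported
    purity is the sample-weighted majority-class fraction of the two
    top-level branches: 1.0 means the cut reproduces the H/L split exactly.
    """
    if on == "matrix":
        data = matrix.values
    elif on == "pcs":
        if result is None:
            raise ValueError('on="pcs" requires a PCAResult')
        data = result.coords.iloc[:, :retained]
    else:
        raise ValueError(f"unknown clustering input {on!r}")
    if data.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    Z = hierarchy.linkage(pdist(data.to_numpy(float), metric=metric),
                          method=linkage_method)
    labels = list(data.index)
    flat = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    classes = matrix.row_classes.reindex(labels)
    correct = 0
    for branch in np.unique(flat):
        members = classes[flat == branch]
        correct += members.value_counts().max()
    purity = correct / len(labels)
    return ClusterTree(linkage=Z, labels=labels, row_classes=classes,
                       purity=float(purity))
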