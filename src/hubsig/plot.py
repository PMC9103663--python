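"""Basic diagnostic plots for fitted results.

All functions take a :class:`~hubsig.model.HubSignatureResults` (or the
relevant stage object) and return a matplotlib ``Figure``; nothing is shown
or saved implicitly.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers can switch backends first
import matplotlib.pyplot as plt
from scipy.cluster import hierarchy

__all__ = ["plot_pca", "plot_dendrogram", "plot_importances"]

_CLASS_COLORS = {"H": "#c0392b", "L": "#27ae60"}


def plot_pca(results, x: str = "PC1", y: str = "PC3"):
    """Cancer types in PC space, colored by aggressiveness class."""
    coords = results.pca.coords
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, row in coords.iterrows():
        cls = results.pca.row_classes[label]
        ax.scatter(row[x], row[y], color=_CLASS_COLORS.get(cls, "gray"), s=60)
        ax.annotate(label, (row[x], row[y]), textcoords="offset points",
                    xytext=(4, 4), fontsize=8)
    props = results.pca.proportions
    ax.set_xlabel(f"{x} ({props[int(x[2:]) - 1] * 100:.1f}%)")
    ax.set_ylabel(f"{y} ({props[int(y[2:]) - 1] * 100:.1f}%)")
    ax.set_title("PCA of normalized connections")
    fig.tight_layout()
    return fig


def plot_dendrogram(results):
    """Hierarchical clustering of cancer types (manhattan distance)."""
    fig, ax = plt.subplots(figsize=(5, 4))
    hierarchy.dendrogram(
        results.cluster.linkage, labels=results.cluster.labels, ax=ax
    )
    for tick in ax.get_xticklabels():
        cls = results.cluster.row_classes.get(tick.get_text())
        tick.set_color(_CLASS_COLORS.get(cls, "black"))
    ax.set_ylabel("merge height")
    ax.set_title(f"HC of cancer types (purity {results.cluster.purity:.2f})")
    fig.tight_layout()
    return fig


def plot_importances(results, top_k: int = 10):
    """Top genes by mean decrease in Gini impurity."""
    from .rfclass import importance_ranking

    table = importance_ranking(results.rfc, top_k=top_k)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.barh(table["gene"][::-1], table["mean_decrease_gini"][::-1],
            color="#34495e")
    ax.set_xlabel("mean decrease in Gini")
    ax.set_title("Random-forest gene importance")
    fig.tight_layout()
    return fig
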