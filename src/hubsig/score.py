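"""Frequency x connectivity gene scoring — the core statistic.

For each gene and group (aggressiveness class H/L, or cancer type) the
*normalized count* is the fraction of the group's samples in which the gene
is upregulated, and the *normalized connections* value multiplies that
frequency by the gene's interactome degree. A gene absent from a group gets
a normalized count of zero rather than being dropped, so class-exclusive
genes — potentially strong severity indicators — stay in play. On top of
these per-gene records sit the variance filter (cross-class variance of
normalized counts, class-exclusive genes always kept), the hub-boundary grid
search for the (connections, frequency) corner occupied exclusively by
H-class genes, and the per-class score totals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .interactome import Interactome, PathwayMap
from .synthcohort import SampleProfile

__all__ = [
    "PathwaySummary",
    "HubBoundary",
    "filter_to_pathways",
    "class_norm_counts",
    "norm_connections",
    "variance_filter",
    "hub_boundary_search",
    "class_score",
]

logger = logging.getLogger(__name__)

#: columns of the tidy gene-by-group statistics table
STAT_COLUMNS = ["gene", "group", "n", "norm_count", "degree", "norm_connections"]


@dataclass(frozen=True)
class PathwaySummary:
    """Partition of the pathway-restricted gene universe by class occurrence."""

    total: int
    h_only: int
    l_only: int
    shared: int

    def __post_init__(self):
        if self.h_only + self.l_only + self.shared != self.total:
            raise ValueError("summary partition does not sum to total")


@dataclass
class HubBoundary:
    """Result of the hub-boundary grid search.

    ``c_star``/``f_star`` are the normalized-connections and normalized-count
    thresholds (both inclusive); under the default exclusivity objective the
    listed genes meet both thresholds in H while no L gene does.
    """

    c_star: float
    f_star: float
    genes: list[str] = field(default_factory=list)
    objective: float = 0.0


def filter_to_pathways(
    profiles: Sequence[SampleProfile], pathways: PathwayMap
) -> tuple[list[SampleProfile], PathwaySummary]:
    """Restrict every sample's upregulated set to the pathway union.

    Returns the filtered profiles plus a summary partitioning the retained
    gene universe into H-only / L-only / shared-by-both-classes.
    """
    if not profiles:
        raise ValueError("no profiles supplied")
    union = pathways.union
    if not union:
        raise ValueError("pathway union is empty")
    filtered = [
        SampleProfile(p.sample_id, p.cancer_type, p.class_label,
                      frozenset(p.genes & union))
        for p in profiles
    ]
    seen_h: set[str] = set()
    seen_l: set[str] = set()
    for p in filtered:
        (seen_h if p.class_label == "H" else seen_l).update(p.genes)
    shared = seen_h & seen_l
    summary = PathwaySummary(
        total=len(seen_h | seen_l),
        h_only=len(seen_h - seen_l),
        l_only=len(seen_l - seen_h),
        shared=len(shared),
    )
    return filtered, summary


def class_norm_counts(
    profiles: Sequence[SampleProfile], group_by: str = "class"
) -> pd.DataFrame:
    """Per-gene, per-group upregulation counts and normalized counts.

    ``group_by`` is ``"class"`` (H/L) or ``"cancer_type"``. Every observed
    gene gets a row in every group; genes never upregulated in a group carry
    n = 0 and norm_count = 0 (null imputation for group-exclusive genes).
    """
    if group_by not in ("class", "cancer_type"):
        raise ValueError(f"unknown group_by {group_by!r}")
    key = (lambda p: p.class_label) if group_by == "class" else (lambda p: p.cancer_type)
    group_sizes: dict[str, int] = {}
    counts: dict[str, dict[str, int]] = {}
    for p in profiles:
        g = key(p)
        group_sizes[g] = group_sizes.get(g, 0) + 1
        bucket = counts.setdefault(g, {})
        for gene in p.genes:
            bucket[gene] = bucket.get(gene, 0) + 1
    all_genes = sorted({gene for bucket in counts.values() for gene in bucket})
    rows = []
    for group in sorted(group_sizes):
        size = group_sizes[group]
        bucket = counts.get(group, {})
        for gene in all_genes:
            n = bucket.get(gene, 0)
            rows.append((gene, group, n, n / size))
    df = pd.DataFrame(rows, columns=["gene", "group", "n", "norm_count"])
    df.attrs["group_sizes"] = group_sizes
    df.attrs["group_by"] = group_by
    return df


def norm_connections(
    stats: pd.DataFrame, interactome: Interactome | Mapping[str, int]
) -> pd.DataFrame:
    """Attach degree and norm_connections = norm_count x degree.

    ``interactome`` may be an :class:`Interactome` or a plain gene -> degree
    mapping (per-gene connection numbers are themselves a standard input
    table). Genes without a degree are excluded with a logged count.
    """
    degrees: Mapping[str, int]
    if isinstance(interactome, Interactome):
        degrees = interactome.degrees()
    else:
        degrees = interactome
    out = stats.copy()
    known = out["gene"].map(lambda g: g in degrees)
    n_missing = int(out.loc[~known, "gene"].nunique())
    if (~known).any():
        logger.warning(
            "%d genes absent from the interactome were excluded from scoring",
            n_missing,
        )
    out = out[known].copy()
    out["degree"] = out["gene"].map(degrees).astype(int)
    out["norm_connections"] = out["norm_count"] * out["degree"]
    out.attrs = dict(stats.attrs)
    out.attrs["n_missing_degree"] = n_missing
    return out.reset_index(drop=True)


def variance_filter(
    stats: pd.DataFrame, threshold: float = 0.005, on: str = "norm_count"
) -> set[str]:
    """Genes with cross-class variance > threshold, plus class-exclusive genes.

    Variance is the unbiased sample variance over the two class values of
    ``on`` (for two values, (x_H - x_L)^2 / 2). Genes upregulated in only one
    class cannot have their spread compared and are always retained.
    """
    if on not in ("norm_count", "norm_connections"):
        raise ValueError(f"unknown variance quantity {on!r}")
    classes = set(stats["group"].unique())
    if not {"H", "L"} <= classes:
        raise ValueError("stats must contain both H and L classes")
    wide_n = stats.pivot(index="gene", columns="group", values="n")
    wide_x = stats.pivot(index="gene", columns="group", values=on)
    in_h = wide_n["H"] > 0
    in_l = wide_n["L"] > 0
    exclusive = wide_n.index[in_h ^ in_l]
    both = wide_n.index[in_h & in_l]
    var = wide_x.loc[both, ["H", "L"]].var(axis=1, ddof=1)
    selected = set(var.index[var > threshold]) | set(exclusive)
    return selected


def hub_boundary_search(
    stats_h: pd.DataFrame,
    stats_l: pd.DataFrame,
    objective: str = "exclusive",
) -> HubBoundary:
    """Grid search for the hub boundary separating H from L.

    Candidate thresholds are the observed (norm_connections, norm_count)
    values in H. The default ``"exclusive"`` objective maximizes the number
    of H genes with norm_connections >= c and norm_count >= f subject to no
    L gene satisfying both; ties prefer larger c, then larger f. With no
    feasible exclusive corner the boundary comes back with an empty gene
    list and objective 0.
    """
    if objective != "exclusive":
        raise ValueError(f"unknown objective {objective!r}")
    h = stats_h[stats_h["n"] > 0]
    l = stats_l[stats_l["n"] > 0]
    if h.empty or l.empty:
        raise ValueError("both class tables must be non-empty")
    hc = h["norm_connections"].to_numpy(float)
    hf = h["norm_count"].to_numpy(float)
    lc = l["norm_connections"].to_numpy(float)
    lf = l["norm_count"].to_numpy(float)
    genes = h["gene"].to_numpy()
    best = HubBoundary(c_star=float("inf"), f_star=float("inf"))
    for c in np.unique(hc):
        h_in_c = hc >= c
        l_in_c = lc >= c
        for f in np.unique(hf[h_in_c]):
            if np.any(l_in_c & (lf >= f)):
                continue
            count = int(np.sum(h_in_c & (hf >= f)))
            if count > best.objective or (
                count == best.objective
                and count > 0
                and (c, f) > (best.c_star, best.f_star)
            ):
                best = HubBoundary(
                    c_star=float(c),
                    f_star=float(f),
                    genes=sorted(genes[h_in_c & (hf >= f)]),
                    objective=float(count),
                )
    if not best.genes:
        return HubBoundary(c_star=float("nan"), f_star=float("nan"))
    return best


def class_score(
    stats: pd.DataFrame, genes: Sequence[str]
) -> tuple[dict[str, float], float]:
    """Per-class normalized-connections totals over a gene list.

    Returns ``({class: total}, relative difference)`` where the relative
    difference is (H - L) / H x 100 — how much larger the aggressive class's
    score is, in percent. A gene absent from a class contributes 0 there.
    """
    genes = list(genes)
    totals: dict[str, float] = {}
    for cls, grp in stats.groupby("group"):
        sub = grp[grp["gene"].isin(genes)]
        totals[str(cls)] = float(sub["norm_connections"].sum())
    totals.setdefault("H", 0.0)
    totals.setdefault("L", 0.0)
    h, l = totals["H"], totals["L"]
    rel = (h - l) / h * 100.0 if h != 0 else float("nan")
    return totals, rel
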