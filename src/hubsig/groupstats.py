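"""Nonparametric cross-group comparison of connection counts per pathway.

Within each signaling pathway, the raw interactome degrees of the upregulated
genes observed in each cancer type are compared across types with a
Kruskal–Wallis rank test, followed by pairwise Wilcoxon rank-sum tests with
Bonferroni correction. By default each upregulation event contributes one
observation (a gene upregulated in ten samples of a type appears ten times —
the distributions being compared are over *occurrences*); ``per_gene=True``
collapses to one observation per distinct gene instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Mapping, Sequence

import pandas as pd
from scipy import stats as sps

from .interactome import Interactome, PathwayMap
from .synthcohort import SampleProfile

__all__ = ["PathwayGroupTest", "pathway_observations", "kruskal_by_pathway",
           "pairwise_wilcoxon"]

#: switch from the exact rank-sum null to the normal approximation with
#: continuity correction above this per-group size
EXACT_MAX_N = 25


@dataclass
class PathwayGroupTest:
    pathway: str
    statistic: float | None = None
    p_value: float | None = None
    pairwise: pd.DataFrame | None = None  # symmetric, Bonferroni-adjusted
    n_comparisons: int = 0
    groups: dict[str, int] = field(default_factory=dict)
    flagged: str | None = None  # reason no test was run


def pathway_observations(
    profiles: Sequence[SampleProfile],
    interactome: Interactome | Mapping[str, int],
    pathways: PathwayMap,
    per_gene: bool = False,
) -> dict[str, dict[str, list[int]]]:
    """pathway -> cancer type -> list of degree observations."""
    degrees = (
        interactome.degrees() if isinstance(interactome, Interactome) else interactome
    )
    obs: dict[str, dict[str, list[int]]] = {
        name: {} for name in pathways
    }
    seen: dict[str, dict[str, set[str]]] = {name: {} for name in pathways}
    for p in profiles:
        for name, members in pathways.items():
            hits = p.genes & members
            bucket = obs[name].setdefault(p.cancer_type, [])
            if per_gene:
                dedup = seen[name].setdefault(p.cancer_type, set())
                hits = hits - dedup
                dedup |= hits
            bucket.extend(degrees[g] for g in sorted(hits) if g in degrees)
    return obs


def _testable(groups: dict[str, list[int]]) -> dict[str, list[int]]:
    return {k: v for k, v in groups.items() if len(v) >= 2}


def kruskal_by_pathway(
    observations: dict[str, dict[str, list[int]]],
) -> list[PathwayGroupTest]:
    """Kruskal–Wallis H test (tie-corrected, chi-squared null) per pathway.

    Pathways with fewer than two groups of at least two observations are
    flagged and carry no p-value.
    """
    results = []
    for pathway in sorted(observations):
        groups = _testable(observations[pathway])
        test = PathwayGroupTest(
            pathway=pathway, groups={k: len(v) for k, v in groups.items()}
        )
        if len(groups) < 2:
            test.flagged = "fewer than 2 groups with >= 2 observations"
        else:
            try:
                h, p = sps.kruskal(*groups.values())
                test.statistic, test.p_value = float(h), float(p)
            except ValueError:  # all values identical across every group
                test.statistic, test.p_value = 0.0, 1.0
        results.append(test)
    return results


def _rank_sum_p(a: Sequence[int], b: Sequence[int]) -> float:
    """Two-sided Wilcoxon rank-sum p-value; exact for small tie-free groups."""
    ties = len(set(a) | set(b)) < len(a) + len(b)
    if max(len(a), len(b)) <= EXACT_MAX_N and not ties:
        method = "exact"
    else:
        method = "asymptotic"  # normal approximation with continuity correction
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def pairwise_wilcoxon(
    observations: dict[str, dict[str, list[int]]],
) -> list[PathwayGroupTest]:
    """All unordered pairwise rank-sum tests within each pathway.

    Adjusted p = min(1, raw p x number of pairs tested in that pathway);
    the returned matrix is symmetric with NaN on the diagonal.
    """
    results = []
    for pathway in sorted(observations):
        groups = _testable(observations[pathway])
        labels = sorted(groups)
        test = PathwayGroupTest(
            pathway=pathway, groups={k: len(v) for k, v in groups.items()}
        )
        if len(labels) < 2:
            test.flagged = "fewer than 2 groups with >= 2 observations"
            results.append(test)
            continue
        n_pairs = len(labels) * (len(labels) - 1) // 2
        mat = pd.DataFrame(float("nan"), index=labels, columns=labels)
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                raw = _rank_sum_p(groups[a], groups[b])
                adj = min(1.0, raw * n_pairs)
                mat.loc[a, b] = mat.loc[b, a] = adj
        test.pairwise = mat
        test.n_comparisons = n_pairs
        results.append(test)
    return results


def tests_to_table(
    kruskal: list[PathwayGroupTest], pairwise: list[PathwayGroupTest]
) -> pd.DataFrame:
    """Flatten results into a tidy (pathway, test, group_a, group_b, p) table."""
    rows = []
    for t in kruskal:
        rows.append(
            ("kruskal", t.pathway, "", "", t.p_value, t.p_value, t.flagged or "")
        )
    for t in pairwise:
        if t.pairwise is None:
            continue
        n = t.n_comparisons
        for i, a in enumerate(t.pairwise.index):
            for b in t.pairwise.columns[i + 1 :]:
                adj = t.pairwise.loc[a, b]
                raw = adj / n if adj < 1.0 else float("nan")
                rows.append(("wilcoxon", t.pathway, a, b, raw, adj, ""))
    return pd.DataFrame(
        rows,
        columns=["test", "pathway", "group_a", "group_b", "raw_p", "adj_p", "note"],
    )
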