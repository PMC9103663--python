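"""Model/Results surface tying the whole analysis together.

``HubSignatureModel`` holds the data (sample profiles, interactome, pathway
map) and the analysis parameters; ``fit()`` runs the full chain — pathway
filtering, class- and type-wise normalization, variance filtering, hub
boundary search, PCA with gene contributions, hierarchical clustering,
random-forest classification, and network mapping of the selected genes —
and returns a ``HubSignatureResults`` carrying every stage's output plus a
``summary()`` table.

    >>> model = HubSignatureModel(profiles, interactome, pathways)
    >>> res = model.fit(seed=1)
    >>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Sequence
from pathlib import Path

import pandas as pd

from . import groupstats, netx, pcaclass, rfclass, score
from .interactome import Interactome, PathwayMap
from .synthcohort import SampleProfile, read_profiles_tsv

__all__ = ["HubSignatureModel", "HubSignatureResults"]


@dataclass
class HubSignatureResults:
    """Everything `HubSignatureModel.fit` computes, in stage order."""

    pathway_summary: score.PathwaySummary
    class_stats: pd.DataFrame  # gene x class normalized counts/connections
    type_stats: pd.DataFrame  # gene x cancer-type, PCA input
    selected_genes: set[str]  # variance-filter survivors
    hub_boundary: score.HubBoundary
    group_tests: list[groupstats.PathwayGroupTest]
    pairwise_tests: list[groupstats.PathwayGroupTest]
    pca: pcaclass.PCAResult
    contributions: pd.DataFrame
    cluster: pcaclass.ClusterTree
    rfc: rfclass.RFCResult
    score_genes: list[str]  # genes contributing >= the contribution cut
    class_scores: dict[str, float]
    score_rel_diff: float  # (H - L)/H x 100
    network: netx.SubNetwork
    bridges: dict[str, list[netx.BridgePath]]
    params: dict = field(default_factory=dict)

    def top_pca_genes(self, k: int = 10) -> list[str]:
        ordered = self.contributions.sort_values("total_share", ascending=False)
        return [str(g) for g in ordered.index[:k]]

    def top_rfc_genes(self, k: int = 10) -> list[str]:
        return [str(g) for g in
                rfclass.importance_ranking(self.rfc, top_k=k)["gene"]]

    def summary(self) -> str:
        b = self.hub_boundary
        lines = [
            "Hub signature analysis",
            "=" * 58,
            f"Pathway genes observed        {self.pathway_summary.total}"
            f"  (H-only {self.pathway_summary.h_only}, "
            f"L-only {self.pathway_summary.l_only}, "
            f"shared {self.pathway_summary.shared})",
            f"Variance-filtered genes       {len(self.selected_genes)}"
            f"  (threshold {self.params.get('variance_threshold')})",
            f"Hub boundary (conn, freq)     ({b.c_star:.3g}, {b.f_star:.3g})"
            f"  -> {len(b.genes)} H-exclusive hubs",
            f"PC variance proportions       "
            + ", ".join(f"{p:.3f}" for p in self.pca.proportions[:3])
            + f"  (cumulative {self.pca.cumulative[min(2, len(self.pca.cumulative) - 1)]:.3f})",
            f"HC 2-branch class purity      {self.cluster.purity:.3f}",
            f"Class scores (H / L)          {self.class_scores.get('H', 0):.1f} / "
            f"{self.class_scores.get('L', 0):.1f}"
            f"  (H larger by {self.score_rel_diff:.0f}%)",
            f"RFC OOB error                 {self.rfc.oob_error * 100:.2f}%"
            f"  (H {self.rfc.class_errors.get('H', float('nan')):.3f}, "
            f"L {self.rfc.class_errors.get('L', float('nan')):.3f};"
            f" mtry={self.rfc.mtry}, ntree={self.rfc.ntree})",
            f"Network major component       {len(self.network.major_component)} genes"
            f" of {len(self.network.nodes)}; "
            f"{sum(1 for v in self.bridges.values() if v)} bridged back",
        ]
        return "\n".join(lines)


class HubSignatureModel:
    """Frequency x connectivity aggressiveness signature of a tumor cohort.

    Parameters
    ----------
    profiles
        Per-sample upregulated-gene calls with cancer type and H/L class.
    interactome
        The reference protein–protein interaction graph.
    pathways
        Signaling-pathway membership; the analysis is restricted to the
        union of these gene sets.
    variance_threshold
        Cross-class variance cut for gene selection (default 0.005).
    variance_on
        Quantity the variance is computed on: ``"norm_count"`` (default) or
        ``"norm_connections"``.
    retained_pcs, mtry, ntree, contribution_cut, min_degree_full,
    max_intermediaries
        Stage parameters; defaults match the published analysis where one is
        stated (mtry 8, ntree 50, 3 PCs, variance > 0.005).
    """

    def __init__(
        self,
        profiles: Sequence[SampleProfile],
        interactome: Interactome,
        pathways: PathwayMap,
        *,
        variance_threshold: float = 0.005,
        variance_on: str = "norm_count",
        retained_pcs: int = 3,
        hc_on: str = "matrix",
        hc_linkage: str = "complete",
        mtry: int = 8,
        ntree: int = 50,
        contribution_cut: float = 1.0,
        min_degree_full: int = 10,
        max_intermediaries: int = 6,
    ):
        if not profiles:
            raise ValueError("no profiles supplied")
        self.profiles = list(profiles)
        self.interactome = interactome
        self.pathways = pathways
        self.params = dict(
            variance_threshold=variance_threshold,
            variance_on=variance_on,
            retained_pcs=retained_pcs,
            hc_on=hc_on,
            hc_linkage=hc_linkage,
            mtry=mtry,
            ntree=ntree,
            contribution_cut=contribution_cut,
            min_degree_full=min_degree_full,
            max_intermediaries=max_intermediaries,
        )

    @classmethod
    def from_tables(
        cls,
        profiles_tsv: str | Path,
        interactome_tsv: str | Path,
        pathways_tsv: str | Path,
        **params,
    ) -> "HubSignatureModel":
        return cls(
            read_profiles_tsv(profiles_tsv),
            Interactome.from_edgelist_tsv(interactome_tsv),
            PathwayMap.from_tsv(pathways_tsv),
            **params,
        )

    def fit(self, seed: int = 0) -> HubSignatureResults:
        p = self.params
        filtered, summary = score.filter_to_pathways(self.profiles, self.pathways)

        class_stats = score.norm_connections(
            score.class_norm_counts(filtered, group_by="class"), self.interactome
        )
        type_stats = score.norm_connections(
            score.class_norm_counts(filtered, group_by="cancer_type"),
            self.interactome,
        )

        selected = score.variance_filter(
            class_stats, threshold=p["variance_threshold"], on=p["variance_on"]
        )
        stats_h = class_stats[class_stats["group"] == "H"]
        stats_l = class_stats[class_stats["group"] == "L"]
        boundary = score.hub_boundary_search(stats_h, stats_l)

        obs = groupstats.pathway_observations(
            filtered, self.interactome, self.pathways
        )
        kw = groupstats.kruskal_by_pathway(obs)
        pw = groupstats.pairwise_wilcoxon(obs)

        row_classes = {
            prof.cancer_type: prof.class_label for prof in self.profiles
        }
        fm = pcaclass.build_feature_matrix(type_stats, selected, row_classes)
        retained = min(p["retained_pcs"], fm.values.shape[0] - 1)
        pca = pcaclass.run_pca(fm)
        contributions = pcaclass.gene_contributions(pca, retained=retained)
        cluster = pcaclass.hierarchical_cluster(
            fm, on=p["hc_on"], result=pca, retained=retained,
            linkage_method=p["hc_linkage"],
        )

        features = rfclass.build_sample_features(
            filtered, self.interactome, sorted(selected)
        )
        rfc = rfclass.train_rfc(
            features, mtry=p["mtry"], ntree=p["ntree"], seed=seed
        )

        score_genes = list(
            contributions.index[
                contributions[[f"PC{k + 1}" for k in range(retained)]].max(axis=1)
                >= p["contribution_cut"]
            ]
        )
        class_scores, rel = score.class_score(class_stats, score_genes)

        pca_top = set(
            contributions.sort_values("total_share", ascending=False).index[:10]
        )
        rfc_top = set(rfclass.importance_ranking(rfc, top_k=10)["gene"])
        sources = {
            g: ("both" if g in pca_top and g in rfc_top
                else "pca" if g in pca_top else "rfc")
            for g in pca_top | rfc_top
        }
        network = netx.extract_subnetwork(
            sorted(pca_top | rfc_top), self.interactome, sources=sources
        )
        network = netx.exclude_low_connectivity(network, p["min_degree_full"])
        bridges = {}
        for gene in sorted(network.nodes - network.major_component):
            bridges[gene] = netx.bridge_paths(
                gene, network, self.interactome,
                max_intermediaries=p["max_intermediaries"],
            )

        return HubSignatureResults(
            pathway_summary=summary,
            class_stats=class_stats,
            type_stats=type_stats,
            selected_genes=selected,
            hub_boundary=boundary,
            group_tests=kw,
            pairwise_tests=pw,
            pca=pca,
            contributions=contributions,
            cluster=cluster,
            rfc=rfc,
            score_genes=score_genes,
            class_scores=class_scores,
            score_rel_diff=rel,
            network=network,
            bridges=bridges,
            params=dict(p, seed=seed),
        )
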