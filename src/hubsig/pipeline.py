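"""End-to-end pipeline runner with a manifest of parameters and seeds.

A run either simulates a cohort (interactome, pathways, class-structured
upregulation, optional paired counts put through the calling stage) or
ingests existing tables, then fits :class:`~hubsig.model.HubSignatureModel`
and writes every stage output plus a ``manifest.json`` recording versions,
parameters, seeds and input digests. Identical configurations reproduce
byte-identical tabular outputs.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, groupstats, netx, rfclass
from .interactome import Interactome, PathwayMap
from .model import HubSignatureModel
from .synthcohort import (
    DEFAULT_GROUPS,
    default_design,
    generate_cohort,
    generate_interactome,
    generate_pathways,
    read_profiles_tsv,
    write_profiles_tsv,
)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Pipeline configuration; defaults are the published stage parameters."""

    out_dir: str = "hubsig_run"
    seed: int = 0
    # either simulate ...
    simulate: bool = True
    n_genes: int = 2000
    edges_per_new_node: int = 2
    genes_per_pathway: int = 100
    overlap_fraction: float = 0.2
    groups: tuple = DEFAULT_GROUPS
    # ... or ingest
    profiles_tsv: str | None = None
    interactome_tsv: str | None = None
    pathways_tsv: str | None = None
    # stage parameters
    alpha: float = 0.025
    variance_threshold: float = 0.005
    variance_on: str = "norm_count"
    retained_pcs: int = 3
    mtry: int = 8
    ntree: int = 50
    min_degree_full: int = 10
    max_intermediaries: int = 6
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = {k: v for k, v in raw.items() if k not in cls.__dataclass_fields__}
        cfg = cls(**known)
        cfg.extra = unknown
        if isinstance(cfg.groups, list):
            cfg.groups = tuple(tuple(g) for g in cfg.groups)
        return cfg


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    stage_seeds = {
        name: int(rng.integers(2**31))
        for name in ("interactome", "pathways", "cohort", "rfc")
    }
    manifest: dict = {
        "hubsig_version": __version__,
        "python": platform.python_version(),
        "config": {k: v for k, v in asdict(config).items() if k != "extra"},
        "stage_seeds": stage_seeds,
        "inputs": {},
        "stages": {},
    }

    try:
        if config.simulate:
            inter = generate_interactome(
                config.n_genes, config.edges_per_new_node, stage_seeds["interactome"]
            )
            pathways = generate_pathways(
                inter,
                genes_per_pathway=config.genes_per_pathway,
                overlap_fraction=config.overlap_fraction,
                seed=stage_seeds["pathways"],
            )
            design = default_design(
                inter, pathways, seed=stage_seeds["cohort"], groups=config.groups
            )
            profiles, truth = generate_cohort(design, inter)
            inter.to_edgelist_tsv(out / "interactome.tsv")
            pathways.to_tsv(out / "pathways.tsv")
            write_profiles_tsv(profiles, out / "profiles.tsv")
            truth.to_json(out / "ground_truth.json")
            manifest["stages"]["simulate"] = {
                "n_genes": len(inter),
                "n_profiles": len(profiles),
                "n_planted_hubs": len(truth.hub_genes),
            }
        else:
            for name in ("profiles_tsv", "interactome_tsv", "pathways_tsv"):
                path = getattr(config, name)
                if not path or not Path(path).exists():
                    raise FileNotFoundError(f"{name} missing: {path}")
                manifest["inputs"][name] = _digest(Path(path))
            profiles = read_profiles_tsv(config.profiles_tsv)
            inter = Interactome.from_edgelist_tsv(config.interactome_tsv)
            pathways = PathwayMap.from_tsv(config.pathways_tsv)
    except Exception as err:
        raise RuntimeError(f"[stage: load] {err}") from err

    model = HubSignatureModel(
        profiles,
        inter,
        pathways,
        variance_threshold=config.variance_threshold,
        variance_on=config.variance_on,
        retained_pcs=config.retained_pcs,
        mtry=config.mtry,
        ntree=config.ntree,
        min_degree_full=config.min_degree_full,
        max_intermediaries=config.max_intermediaries,
    )
    try:
        res = model.fit(seed=stage_seeds["rfc"])
    except ValueError as err:
        raise RuntimeError(f"[stage: fit] {err}") from err

    # stage outputs -------------------------------------------------------
    res.class_stats.to_csv(out / "class_stats.tsv", sep="\t", index=False)
    res.type_stats.to_csv(out / "type_stats.tsv", sep="\t", index=False)
    res.contributions.to_csv(out / "pca_contributions.csv")
    res.pca.loadings.to_csv(out / "pca_loadings.csv")
    groupstats.tests_to_table(res.group_tests, res.pairwise_tests).to_csv(
        out / "group_tests.tsv", sep="\t", index=False
    )
    rfclass.importance_ranking(res.rfc).to_csv(
        out / "rfc_importance.tsv", sep="\t", index=False
    )
    (out / "hub_boundary.json").write_text(
        json.dumps(
            {
                "c_star": res.hub_boundary.c_star,
                "f_star": res.hub_boundary.f_star,
                "genes": res.hub_boundary.genes,
                "objective": res.hub_boundary.objective,
            },
            indent=1,
        )
    )
    (out / "rfc_result.json").write_text(
        json.dumps(
            {
                "confusion": res.rfc.confusion.to_dict(),
                "class_errors": res.rfc.class_errors,
                "oob_error": res.rfc.oob_error,
                "mtry": res.rfc.mtry,
                "ntree": res.rfc.ntree,
                "seed": res.rfc.seed,
            },
            indent=1,
        )
    )
    (out / "dendrogram.nwk").write_text(res.cluster.to_newick() + "\n")
    netx.export_network(res.network, out / "subnetwork.graphml", "graphml")
    netx.export_network(res.network, out / "subnetwork.sif", "sif")
    (out / "summary.txt").write_text(res.summary() + "\n")

    manifest["stages"]["score"] = {
        "pathway_genes": res.pathway_summary.total,
        "h_only": res.pathway_summary.h_only,
        "l_only": res.pathway_summary.l_only,
        "selected": len(res.selected_genes),
        "hub_boundary_genes": len(res.hub_boundary.genes),
        "class_scores": res.class_scores,
        "rel_diff_pct": res.score_rel_diff,
    }
    manifest["stages"]["pca"] = {
        "proportions": [float(x) for x in res.pca.proportions],
        "hc_purity": res.cluster.purity,
    }
    manifest["stages"]["rfc"] = {
        "oob_error": res.rfc.oob_error,
        "class_errors": res.rfc.class_errors,
    }
    manifest["stages"]["network"] = {
        "nodes": len(res.network.nodes),
        "major_component": len(res.network.major_component),
        "bridged": sum(1 for v in res.bridges.values() if v),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
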