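"""Synthetic cohorts with planted ground truth.

Every downstream stage of the aggressiveness-signature analysis is exercised
against data generated here: a scale-free interactome grown by preferential
attachment, overlapping pathway annotations, per-sample Bernoulli
upregulation with class-dependent gene frequencies (hub genes enriched in
the aggressive H class), and paired tumor/control negative-binomial count
tables with planted fold-changes for the upregulation-calling stage.

The default cohort design mirrors the six-tissue layout of the real study:
three H-class pseudo-tissues of 27/48/50 samples and three L-class
pseudo-tissues of 31/56/48 samples (125 H vs 135 L in total). These sizes,
like every distributional choice in this module, are stand-ins — the real
analysis runs on patient cohorts for which no generative model exists.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .interactome import CANONICAL_PATHWAYS, Interactome, PathwayMap

__all__ = [
    "SampleProfile",
    "CohortDesign",
    "GroundTruth",
    "generate_interactome",
    "generate_pathways",
    "generate_cohort",
    "generate_paired_counts",
    "default_design",
    "write_profiles_tsv",
    "read_profiles_tsv",
]

#: (cancer-type label, class label, sample count) mirroring the real cohorts.
DEFAULT_GROUPS: tuple[tuple[str, str, int], ...] = (
    ("STAD", "H", 27),
    ("LUSC", "H", 48),
    ("LIHC", "H", 50),
    ("KIRP", "L", 31),
    ("THCA", "L", 56),
    ("PRAD", "L", 48),
)


@dataclass(frozen=True)
class SampleProfile:
    """One tumor sample: identity plus its set of upregulated genes."""

    sample_id: str
    cancer_type: str
    class_label: str  # "H" or "L"
    genes: frozenset[str]

    def __post_init__(self):
        if self.class_label not in ("H", "L"):
            raise ValueError(f"class label must be H or L, got {self.class_label!r}")


@dataclass
class CohortDesign:
    """Class-structured Bernoulli upregulation design.

    ``freq`` maps gene -> {"H": p_H, "L": p_L}; a frequency of exactly 0 in
    one class makes the gene class-exclusive. ``type_effects`` optionally
    perturbs a gene's frequency per cancer type (multiplicative, clipped to
    [0, 1]) so that per-type rows are not identical within a class.
    """

    groups: tuple[tuple[str, str, int], ...]
    freq: dict[str, dict[str, float]]
    seed: int = 0
    type_effects: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        for _, cls, n in self.groups:
            if cls not in ("H", "L"):
                raise ValueError(f"class label must be H or L, got {cls!r}")
            if n <= 0:
                raise ValueError("sample counts must be positive")
        for gene, by_class in self.freq.items():
            for p in by_class.values():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"frequency for {gene} outside [0,1]: {p}")

    def n_samples(self, class_label: str | None = None) -> int:
        return sum(
            n for _, cls, n in self.groups if class_label in (None, cls)
        )


@dataclass
class GroundTruth:
    """Planted parameters, recorded before any sampling."""

    freq: dict[str, dict[str, float]] = field(default_factory=dict)
    hub_genes: list[str] = field(default_factory=list)
    hub_degrees: dict[str, int] = field(default_factory=dict)
    fold_change: dict[str, float] = field(default_factory=dict)
    upregulated: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "freq": self.freq,
                    "hub_genes": self.hub_genes,
                    "hub_degrees": self.hub_degrees,
                    "fold_change": self.fold_change,
                    "upregulated": self.upregulated,
                },
                fh,
                indent=1,
            )


# ---------------------------------------------------------------------------
# interactome
# ---------------------------------------------------------------------------

def generate_interactome(
    n_genes: int, edges_per_new_node: int, seed: int
) -> Interactome:
    """Grow a connected scale-free graph by preferential attachment.

    Starts from a clique on ``edges_per_new_node + 1`` nodes; each new node
    attaches to ``edges_per_new_node`` distinct existing nodes sampled with
    probability proportional to current degree. The result has the heavy
    right degree tail characteristic of signaling networks: few hubs, many
    low-degree genes.
    """
    m = int(edges_per_new_node)
    n = int(n_genes)
    if m < 1:
        raise ValueError("edges_per_new_node must be >= 1")
    if n <= m:
        raise ValueError("n_genes must exceed edges_per_new_node")
    rng = np.random.default_rng(seed)

    width = max(4, len(str(n)))
    names = [f"G{i + 1:0{width}d}" for i in range(n)]
    degrees = np.zeros(n, dtype=np.int64)
    edges: list[tuple[str, str]] = []

    # seed clique
    for i in range(m + 1):
        for j in range(i + 1, m + 1):
            edges.append((names[i], names[j]))
    degrees[: m + 1] = m

    for new in range(m + 1, n):
        probs = degrees[:new] / degrees[:new].sum()
        targets = rng.choice(new, size=m, replace=False, p=probs)
        for t in targets:
            edges.append((names[t], names[new]))
            degrees[t] += 1
        degrees[new] = m

    return Interactome(edges, nodes=names)


# ---------------------------------------------------------------------------
# pathways
# ---------------------------------------------------------------------------

def generate_pathways(
    interactome: Interactome,
    pathway_names: tuple[str, ...] = CANONICAL_PATHWAYS,
    genes_per_pathway: int = 100,
    overlap_fraction: float = 0.2,
    seed: int = 0,
) -> PathwayMap:
    """Overlapping pathway annotations over the interactome's genes.

    A shared core of ``round(overlap_fraction * genes_per_pathway)`` genes is
    placed in every pathway, so each pairwise intersection equals the
    requested overlap exactly; the remaining members are pathway-exclusive.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0, 1]")
    size = int(genes_per_pathway)
    if size < 1:
        raise ValueError("genes_per_pathway must be positive")
    k_core = round(overlap_fraction * size)
    n_exclusive = size - k_core
    needed = k_core + n_exclusive * len(pathway_names)
    genes = sorted(interactome.genes)
    if needed > len(genes):
        raise ValueError(
            f"need {needed} genes for {len(pathway_names)} pathways of size "
            f"{size} at overlap {overlap_fraction}, interactome has {len(genes)}"
        )
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(genes), size=needed, replace=False)
    pool = [genes[i] for i in picked]
    core = set(pool[:k_core])
    members: dict[str, set[str]] = {}
    offset = k_core
    for name in pathway_names:
        members[name] = core | set(pool[offset : offset + n_exclusive])
        offset += n_exclusive
    return PathwayMap(members)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def generate_cohort(
    design: CohortDesign, interactome: Interactome
) -> tuple[list[SampleProfile], GroundTruth]:
    """Draw per-sample upregulated gene sets from the design frequencies.

    Each gene is an independent Bernoulli event per sample at the gene's
    class frequency (optionally modulated per cancer type); empirical class
    frequencies converge to the design values as sample counts grow.
    """
    unknown = [g for g in design.freq if g not in interactome]
    if unknown:
        raise ValueError(
            f"{len(unknown)} design genes absent from interactome, "
            f"e.g. {unknown[:3]}"
        )
    rng = np.random.default_rng(design.seed)
    genes = np.array(sorted(design.freq))
    base = {
        cls: np.array([design.freq[g].get(cls, 0.0) for g in genes])
        for cls in ("H", "L")
    }
    profiles: list[SampleProfile] = []
    for cancer_type, cls, n in design.groups:
        p = base[cls].copy()
        effects = design.type_effects.get(cancer_type)
        if effects:
            mult = np.array([effects.get(g, 1.0) for g in genes])
            p = np.clip(p * mult, 0.0, 1.0)
        for i in range(n):
            up = genes[rng.random(len(genes)) < p]
            profiles.append(
                SampleProfile(
                    sample_id=f"{cancer_type}_{i + 1:03d}",
                    cancer_type=cancer_type,
                    class_label=cls,
                    genes=frozenset(up),
                )
            )
    degrees = interactome.degrees()
    truth = GroundTruth(
        freq={g: dict(design.freq[g]) for g in design.freq},
        hub_genes=[
            g
            for g in design.freq
            if design.freq[g].get("H", 0) > design.freq[g].get("L", 0)
            and degrees.get(g, 0)
            >= float(np.quantile(list(degrees.values()), 0.9))
        ],
        hub_degrees={},
    )
    truth.hub_degrees = {g: degrees[g] for g in truth.hub_genes}
    return profiles, truth


def default_design(
    interactome: Interactome,
    pathways: PathwayMap,
    seed: int = 0,
    *,
    groups: tuple[tuple[str, str, int], ...] = DEFAULT_GROUPS,
    hub_quantile: float = 0.9,
    hub_freq_h: float = 0.8,
    hub_freq_l: float = 0.25,
    base_freq_low: float = 0.02,
    base_freq_high: float = 0.45,
    exclusive_fraction: float = 0.15,
    type_jitter: float = 0.15,
) -> CohortDesign:
    """Standard study-condition design over a synthetic interactome.

    Pathway genes get a baseline upregulation frequency shared by both
    classes (uniform on [base_freq_low, base_freq_high]); genes above the
    ``hub_quantile`` degree cut are planted as H-enriched hubs (frequency
    ``hub_freq_h`` in H vs ``hub_freq_l`` in L — the strong-effect regime in
    which hubs dominate the class signal, as they do in the aggressive class
    of the real cohorts); a fraction of non-hub genes is made class-exclusive
    by zeroing one class. Mild per-type multiplicative jitter keeps the six
    pseudo-tissues distinguishable without moving class-level frequencies.
    """
    rng = np.random.default_rng(seed)
    degrees = interactome.degrees()
    genes = sorted(pathways.union & interactome.genes)
    if not genes:
        raise ValueError("no pathway gene overlaps the interactome")
    cut = float(np.quantile([degrees[g] for g in genes], hub_quantile))
    freq: dict[str, dict[str, float]] = {}
    non_hubs = []
    for g in genes:
        if degrees[g] >= cut:
            freq[g] = {"H": hub_freq_h, "L": hub_freq_l}
        else:
            p = float(rng.uniform(base_freq_low, base_freq_high))
            freq[g] = {"H": p, "L": p}
            non_hubs.append(g)
    n_excl = int(exclusive_fraction * len(non_hubs))
    excl = rng.choice(len(non_hubs), size=n_excl, replace=False)
    for j, idx in enumerate(excl):
        g = non_hubs[idx]
        # mirror the real data's asymmetry: more H-only than L-only genes
        if j % 5 < 3:
            freq[g] = {"H": freq[g]["H"] + 0.1, "L": 0.0}
        else:
            freq[g] = {"H": 0.0, "L": freq[g]["L"] + 0.1}
    type_effects: dict[str, dict[str, float]] = {}
    for cancer_type, _, _ in groups:
        mult = rng.uniform(1 - type_jitter, 1 + type_jitter, size=len(genes))
        type_effects[cancer_type] = dict(zip(genes, mult.tolist()))
    return CohortDesign(
        groups=tuple(groups), freq=freq, seed=int(rng.integers(2**31)),
        type_effects=type_effects,
    )


# ---------------------------------------------------------------------------
# paired counts
# ---------------------------------------------------------------------------

def generate_paired_counts(
    n_genes: int,
    n_pairs: int,
    dispersion: float,
    planted_up_fraction: float,
    fold_change: float,
    seed: int,
    mean_log_expr: float = 3.0,
    sd_log_expr: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, GroundTruth]:
    """Negative-binomial paired tumor/control counts with planted signal.

    Per-gene expected control expression is log-normal; counts scale with a
    gene's coding-sequence length (so length normalization is a real step,
    not a no-op). Planted genes have tumor mean = ``fold_change`` x control
    mean; all counts are Gamma–Poisson draws with common ``dispersion``
    (variance mu + dispersion * mu^2).
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if fold_change <= 1:
        raise ValueError("fold_change must exceed 1")
    if not 0.0 <= planted_up_fraction <= 1.0:
        raise ValueError("planted_up_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_genes, n_pairs = int(n_genes), int(n_pairs)
    width = max(4, len(str(n_genes)))
    genes = [f"G{i + 1:0{width}d}" for i in range(n_genes)]
    lengths = pd.Series(
        rng.integers(300, 3000, size=n_genes), index=genes, name="cds_length"
    )
    base_expr = np.exp(rng.normal(mean_log_expr, sd_log_expr, size=n_genes))
    n_up = int(round(planted_up_fraction * n_genes))
    up_idx = rng.choice(n_genes, size=n_up, replace=False)
    fc = np.ones(n_genes)
    fc[up_idx] = fold_change

    mu_control = base_expr * lengths.to_numpy() / 1000.0
    mu_tumor = mu_control * fc
    r = 1.0 / dispersion

    def draw(mu: np.ndarray) -> np.ndarray:
        lam = rng.gamma(shape=r, scale=np.tile(mu, (n_pairs, 1)).T / r)
        return rng.poisson(lam)

    pair_ids = [f"P{j + 1:03d}" for j in range(n_pairs)]
    tumor = pd.DataFrame(draw(mu_tumor), index=genes, columns=pair_ids)
    control = pd.DataFrame(draw(mu_control), index=genes, columns=pair_ids)
    truth = GroundTruth(
        fold_change={genes[i]: float(fc[i]) for i in range(n_genes)},
        upregulated=sorted(genes[i] for i in up_idx),
    )
    return tumor, control, lengths, truth


# ---------------------------------------------------------------------------
# profile I/O
# ---------------------------------------------------------------------------

def write_profiles_tsv(profiles: list[SampleProfile], path: str | Path) -> None:
    """One row per (sample, upregulated gene); samples with no genes still
    appear once with an empty gene field so group sizes survive a round trip."""
    with open(path, "w") as fh:
        fh.write("sample_id\tcancer_type\tclass\tgene\n")
        for p in profiles:
            if not p.genes:
                fh.write(f"{p.sample_id}\t{p.cancer_type}\t{p.class_label}\t\n")
            for g in sorted(p.genes):
                fh.write(f"{p.sample_id}\t{p.cancer_type}\t{p.class_label}\t{g}\n")


def read_profiles_tsv(path: str | Path) -> list[SampleProfile]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    profiles = []
    for (sid, ctype, cls), grp in df.groupby(
        ["sample_id", "cancer_type", "class"], sort=False
    ):
        genes = frozenset(g for g in grp["gene"] if g)
        profiles.append(SampleProfile(sid, ctype, cls, genes))
    return profiles
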