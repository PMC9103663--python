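"""Sub-interactome extraction and bridging-path discovery.

The genes selected by the variance (PCA) and classification (RFC) stages are
mapped back onto the full interactome: the induced subgraph is split into
connected components, nodes whose *full-interactome* degree falls below a
threshold are set aside as uninformative low-connectivity genes, and genes
left outside the major component are connected back to it through shortest
paths whose intermediaries are interactome proteins outside the selected
list. Outputs are Cytoscape-readable (GraphML, SIF).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from collections.abc import Mapping, Sequence

import networkx as nx

from .interactome import Interactome

__all__ = [
    "SubNetwork",
    "BridgePath",
    "extract_subnetwork",
    "exclude_low_connectivity",
    "bridge_paths",
    "export_network",
    "import_graphml",
]


@dataclass
class SubNetwork:
    """Induced subgraph with component labels and provenance annotations."""

    graph: nx.Graph  # node attrs: source, degree_full, degree_sub, component
    major_component: frozenset[str] = frozenset()

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def components(self) -> list[frozenset[str]]:
        comps = [frozenset(c) for c in nx.connected_components(self.graph)]
        return sorted(comps, key=lambda c: (-len(c), tuple(sorted(c))))


@dataclass
class BridgePath:
    origin: str
    terminal: str  # first node reached inside the major component
    intermediaries: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.intermediaries) + 1


def _label_components(graph: nx.Graph) -> frozenset[str]:
    """Assign component indices (major first, deterministic tie-break)."""
    comps = sorted(
        (frozenset(c) for c in nx.connected_components(graph)),
        key=lambda c: (-len(c), tuple(sorted(c))),
    )
    for idx, comp in enumerate(comps):
        for node in comp:
            graph.nodes[node]["component"] = idx
    return comps[0] if comps else frozenset()


def extract_subnetwork(
    genes: Sequence[str],
    interactome: Interactome,
    sources: Mapping[str, str] | None = None,
) -> SubNetwork:
    """Induced subgraph of the interactome on the listed genes.

    ``sources`` optionally annotates each gene with its selection provenance
    (e.g. "pca", "rfc", "both"). The major component is the largest one;
    equal sizes break toward the lexicographically smallest member set.
    """
    present = [g for g in dict.fromkeys(genes) if g in interactome]
    if not present:
        raise ValueError("no listed gene is present in the interactome")
    sub = nx.Graph(interactome.graph.subgraph(present).copy())
    for node in sub.nodes:
        sub.nodes[node]["source"] = (sources or {}).get(node, "selected")
        sub.nodes[node]["degree_full"] = interactome.degree(node)
        sub.nodes[node]["degree_sub"] = int(sub.degree[node])
    major = _label_components(sub)
    return SubNetwork(graph=sub, major_component=major)


def exclude_low_connectivity(
    network: SubNetwork, min_degree_full: int
) -> SubNetwork:
    """Drop nodes whose full-interactome degree is below the threshold.

    The real analysis set aside selected genes with only a handful of
    interactome partners before drawing the network; the cut is a parameter
    (default 10 in the pipeline — a heuristic reconstruction).
    """
    keep = [
        n
        for n in network.graph.nodes
        if network.graph.nodes[n]["degree_full"] >= min_degree_full
    ]
    sub = nx.Graph(network.graph.subgraph(keep).copy())
    for node in sub.nodes:
        sub.nodes[node]["degree_sub"] = int(sub.degree[node])
    major = _label_components(sub)
    return SubNetwork(graph=sub, major_component=major)


def bridge_paths(
    origin: str,
    network: SubNetwork,
    interactome: Interactome,
    max_intermediaries: int = 6,
    policy: str = "shortest",
) -> list[BridgePath]:
    """Paths reconnecting an isolated selected gene to the major component.

    Searches the *full* interactome from ``origin`` to any major-component
    node, allowing only non-selected genes as intermediaries. ``"shortest"``
    returns every shortest such path (there may be several); ``"all_simple"``
    returns all simple paths within the intermediary bound. Returns an empty
    list when nothing connects within the bound.
    """
    if origin in network.major_component:
        raise ValueError(f"{origin} is already in the major component")
    if origin not in interactome:
        raise ValueError(f"{origin} absent from interactome")
    allowed = (
        (interactome.genes - network.nodes) | {origin} | network.major_component
    )
    search = interactome.graph.subgraph(allowed)
    targets = network.major_component
    paths: list[list[str]] = []
    if policy == "shortest":
        # BFS truncated at the first level that reaches the component
        try:
            lengths = nx.single_source_shortest_path_length(
                search, origin, cutoff=max_intermediaries + 1
            )
        except nx.NodeNotFound:
            return []
        reached = [t for t in targets if t in lengths]
        if not reached:
            return []
        best = min(lengths[t] for t in reached)
        for t in sorted(t for t in reached if lengths[t] == best):
            for p in nx.all_shortest_paths(search, origin, t):
                # discard routes that brush the component before the terminal
                if any(n in targets for n in p[1:-1]):
                    continue
                paths.append(p)
    elif policy == "all_simple":
        for t in sorted(targets):
            for p in nx.all_simple_paths(
                search, origin, t, cutoff=max_intermediaries + 1
            ):
                if any(n in targets for n in p[1:-1]):
                    continue
                paths.append(p)
    else:
        raise ValueError(f"unknown path policy {policy!r}")
    out = [
        BridgePath(origin=p[0], terminal=p[-1], intermediaries=list(p[1:-1]))
        for p in paths
        if len(p) - 2 <= max_intermediaries
    ]
    out.sort(key=lambda bp: (bp.length, bp.terminal, tuple(bp.intermediaries)))
    return out


def export_network(network: SubNetwork, path: str | Path, format: str = "graphml") -> None:
    """Write the subnetwork for Cytoscape (GraphML with annotations, or SIF)."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(network.graph, path)
    elif format == "sif":
        with open(path, "w") as fh:
            seen: set[str] = set()
            for a, b in sorted(tuple(sorted(e)) for e in network.graph.edges):
                fh.write(f"{a}\tpp\t{b}\n")
                seen |= {a, b}
            for node in sorted(network.nodes - seen):
                fh.write(f"{node}\n")
    else:
        raise ValueError(f"unsupported format {format!r}")


def import_graphml(path: str | Path) -> SubNetwork:
    g = nx.read_graphml(path)
    g = nx.relabel_nodes(g, str)
    major = _label_components(g)
    return SubNetwork(graph=g, major_component=major)
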