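"""Protein–protein interactome and signaling-pathway membership containers.

The interactome is an undirected gene–gene graph; a gene's *degree* (its
number of distinct interaction partners) is the connectivity that the
frequency-weighted hub score multiplies into. Pathway membership is a plain
name -> gene-set mapping; a gene may sit in several pathways (the eight
cross-linked signaling pathways — WNT, EGF, FGF, HEDGEHOG, mTOR, NF-κB,
NOTCH, TGF-β — overlap heavily in the real annotation databases).
"""

from __future__ import annotations

import re
from collections.abc import Iterable, Mapping
from pathlib import Path

import networkx as nx

__all__ = ["Interactome", "PathwayMap", "read_mitab"]

CANONICAL_PATHWAYS = (
    "WNT",
    "EGF",
    "FGF",
    "HEDGEHOG",
    "mTOR",
    "NF-kB",
    "NOTCH",
    "TGF-beta",
)


class Interactome:
    """Undirected interaction graph over gene identifiers.

    Thin wrapper around :class:`networkx.Graph` enforcing the invariants the
    downstream statistics rely on: no self-loops, string node identifiers,
    degree = number of distinct neighbors.
    """

    def __init__(self, edges: Iterable[tuple[str, str]] = (), nodes: Iterable[str] = ()):
        g = nx.Graph()
        g.add_nodes_from(str(n) for n in nodes)
        for a, b in edges:
            a, b = str(a), str(b)
            if a == b:
                continue  # self-interactions carry no connectivity information here
            g.add_edge(a, b)
        self.graph = g

    # -- construction -----------------------------------------------------
    @classmethod
    def from_graph(cls, graph: nx.Graph) -> "Interactome":
        inter = cls()
        inter.graph = nx.Graph()
        inter.graph.add_nodes_from(str(n) for n in graph.nodes)
        inter.graph.add_edges_from(
            (str(a), str(b)) for a, b in graph.edges if a != b
        )
        return inter

    @classmethod
    def from_edgelist_tsv(cls, path: str | Path) -> "Interactome":
        """Read a two-column tab-separated edge list (header optional)."""
        edges = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"malformed edge line: {line!r}")
                if parts[0].lower() in {"gene_a", "source", "node1"}:
                    continue
                edges.append((parts[0], parts[1]))
        return cls(edges)

    def to_edgelist_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_a\tgene_b\n")
            for a, b in sorted(tuple(sorted(e)) for e in self.graph.edges):
                fh.write(f"{a}\t{b}\n")

    # -- queries ----------------------------------------------------------
    @property
    def genes(self) -> set[str]:
        return set(self.graph.nodes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def degree(self, gene: str) -> int:
        return int(self.graph.degree[gene])

    def degrees(self) -> dict[str, int]:
        return {g: int(d) for g, d in self.graph.degree}


class PathwayMap(dict):
    """Mapping of pathway name -> set of member genes."""

    def __init__(self, members: Mapping[str, Iterable[str]] | None = None):
        super().__init__()
        for name, genes in (members or {}).items():
            self[str(name)] = set(map(str, genes))

    @property
    def union(self) -> set[str]:
        out: set[str] = set()
        for genes in self.values():
            out |= genes
        return out

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PathwayMap":
        """Read a two-column (pathway, gene) table, header optional."""
        members: dict[str, set[str]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                pathway, gene = line.split("\t")[:2]
                if pathway.lower() == "pathway":
                    continue
                members.setdefault(pathway, set()).add(gene)
        return cls(members)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("pathway\tgene\n")
            for pathway in sorted(self):
                for gene in sorted(self[pathway]):
                    fh.write(f"{pathway}\t{gene}\n")


_GENE_NAME_RE = re.compile(r":([^:|()]+)\(gene name\)")


def _mitab_symbol(id_field: str, alias_field: str) -> str | None:
    """Best-effort gene symbol from a MITAB interactor column pair."""
    m = _GENE_NAME_RE.search(alias_field)
    if m:
        return m.group(1)
    first = id_field.split("|")[0].strip()
    if not first or first == "-":
        return None
    return first.split(":", 1)[-1]


def read_mitab(path: str | Path) -> Interactome:
    """Build an interactome from a MITAB-flavored interaction table.

    Uses the ``(gene name)`` alias when present (IntAct convention), falling
    back to the primary interactor identifier. Rows without two resolvable
    interactors are skipped.
    """
    edges = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 2:
                continue
            alias_a = cols[4] if len(cols) > 4 else ""
            alias_b = cols[5] if len(cols) > 5 else ""
            a = _mitab_symbol(cols[0], alias_a)
            b = _mitab_symbol(cols[1], alias_b)
            if a and b and a != b:
                edges.append((a, b))
    return Interactome(edges)
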