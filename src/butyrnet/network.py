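"""Zero-order PPI subnetwork construction, miRNA-edge integration, hub ranking.

A :class:`RegulatoryNetwork` is a mixed graph: undirected protein-protein
edges among seed proteins plus miRNA -> protein regulatory edges.  Degrees
count all incident edges of both kinds (the "number of connections" sense),
so integrating miRNA edges raises target-gene degrees.  A PPI-only degree is
also reported for protein nodes.

Zero-order extraction keeps exactly the interactome edges with both endpoints
in the seed set and drops proteins left without any connection; no neighbour
expansion is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import networkx as nx

from .consensus import ConsensusInteraction

RELATION_PPI = "pp"
RELATION_MIRNA_TARGET = "mt"


@dataclass
class RegulatoryNetwork:
    """Mixed PPI + miRNA-target graph with typed nodes.

    Backed by an undirected :class:`networkx.Graph`; regulatory edges are
    tagged ``relation="mt"`` and conventionally read miRNA -> protein.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    # -- construction -------------------------------------------------
    def add_protein(self, node: str, direction: str | None = None) -> None:
        self.graph.add_node(node, kind="protein", direction=direction)

    def add_mirna(self, node: str, direction: str | None = None) -> None:
        self.graph.add_node(node, kind="mirna", direction=direction)

    def add_ppi_edge(self, a: str, b: str) -> None:
        if a == b:
            raise ValueError(f"self-loop rejected: {a}")
        for n in (a, b):
            if self.graph.nodes.get(n, {}).get("kind") == "mirna":
                raise ValueError(f"PPI edge endpoint {n} is a miRNA node")
            if n not in self.graph:
                self.add_protein(n)
        self.graph.add_edge(a, b, relation=RELATION_PPI)

    def add_regulatory_edge(self, mirna: str, gene: str) -> None:
        if mirna == gene:
            raise ValueError(f"self-loop rejected: {mirna}")
        if self.graph.nodes.get(gene, {}).get("kind") == "mirna":
            raise ValueError(f"regulatory edge target {gene} is a miRNA node")
        if mirna not in self.graph:
            self.add_mirna(mirna)
        if gene not in self.graph:
            self.add_protein(gene)
        self.graph.add_edge(mirna, gene, relation=RELATION_MIRNA_TARGET)

    # -- queries ------------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def degree(self, node: str) -> int:
        return self.graph.degree(node)

    def ppi_degree(self, node: str) -> int:
        return sum(
            1
            for _, _, rel in self.graph.edges(node, data="relation")
            if rel == RELATION_PPI
        )

    def edges(self, relation: str | None = None) -> list[tuple[str, str]]:
        if relation is None:
            return [(a, b) for a, b in self.graph.edges]
        return [
            (a, b)
            for a, b, rel in self.graph.edges(data="relation")
            if rel == relation
        ]

    def kind(self, node: str) -> str:
        return self.graph.nodes[node]["kind"]


def zero_order_subnetwork(
    seed_genes: set[str],
    interactome: Iterable[tuple[str, str]],
    min_degree: int = 1,
) -> RegulatoryNetwork:
    """Extract the zero-order PPI subnetwork of a seed gene set.

    Keeps exactly the interactome edges with both endpoints among the seeds;
    proteins whose degree falls below ``min_degree`` are removed.
    """
    if not seed_genes:
        raise ValueError("seed gene set must be non-empty")
    net = RegulatoryNetwork()
    for a, b in interactome:
        if a == b:
            continue
        if a in seed_genes and b in seed_genes:
            net.add_ppi_edge(a, b)
    drop = [n for n in net.graph.nodes if net.graph.degree(n) < min_degree]
    net.graph.remove_nodes_from(drop)
    return net


def integrate_mirna_edges(
    network: RegulatoryNetwork,
    interactions: Iterable[ConsensusInteraction],
    add_missing_genes: bool = False,
) -> RegulatoryNetwork:
    """Add miRNA nodes and miRNA -> target edges to a PPI network.

    By default only interactions whose target gene is already a network node
    are added; with ``add_missing_genes`` the gene node is created too.
    Returns a new network; the input is not modified.
    """
    out = RegulatoryNetwork(network.graph.copy())
    for ia in interactions:
        if ia.gene_id not in out.graph and not add_missing_genes:
            continue
        if ia.gene_id not in out.graph:
            out.add_protein(ia.gene_id, direction=ia.gene_direction)
        out.add_mirna(ia.mirna_id, direction=ia.mirna_direction)
        out.add_regulatory_edge(ia.mirna_id, ia.gene_id)
    return out


def rank_hubs(network: RegulatoryNetwork, top_k: int) -> list[tuple[str, int]]:
    """Top-k nodes by total degree, ties broken by identifier ascending."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if not network.graph.nodes:
        raise ValueError("network is empty")
    ranked = sorted(network.graph.nodes, key=lambda n: (-network.degree(n), n))
    return [(n, network.degree(n)) for n in ranked[:top_k]]


# ---------------------------------------------------------------------------
# import / export


def read_edge_list(path) -> list[tuple[str, str]]:
    """Read an interactome from SIF (3+ columns) or a 2-column TSV."""
    edges: list[tuple[str, str]] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) >= 3:  # SIF: source relation target [target...]
            src, targets = parts[0], parts[2:]
            edges.extend((src, t) for t in targets)
        elif len(parts) == 2:
            edges.append((parts[0], parts[1]))
        else:
            raise ValueError(f"unparseable edge line: {line!r}")
    return edges


def export_network(
    network: RegulatoryNetwork,
    path,
    format: Literal["sif", "graphml", "tsv"] = "sif",
) -> None:
    """Write a network as SIF (+ node-attribute sidecar), GraphML, or TSV.

    Edge emission is sorted so identical networks serialize byte-identically.
    An empty network is an error rather than an empty file.
    """
    if not network.graph.nodes:
        raise ValueError("refusing to export an empty network")
    path = Path(path)
    if format == "sif":
        lines = []
        for a, b, rel in sorted(
            (_canonical(a, b, rel, network) + (rel,))
            for a, b, rel in network.graph.edges(data="relation")
        ):
            lines.append(f"{a}\t{rel}\t{b}")
        path.write_text("\n".join(lines) + "\n")
        _write_node_attrs(network, path.with_suffix(path.suffix + ".attrs.tsv"))
    elif format == "tsv":
        lines = ["source\trelation\ttarget"]
        for a, b, rel in sorted(
            (_canonical(a, b, rel, network) + (rel,))
            for a, b, rel in network.graph.edges(data="relation")
        ):
            lines.append(f"{a}\t{rel}\t{b}")
        path.write_text("\n".join(lines) + "\n")
    elif format == "graphml":
        g = nx.Graph()
        for n, data in network.graph.nodes(data=True):
            g.add_node(
                n,
                kind=data.get("kind", "protein"),
                direction=data.get("direction") or "",
                degree=network.degree(n),
            )
        for a, b, rel in network.graph.edges(data="relation"):
            g.add_edge(a, b, relation=rel)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown export format: {format!r}")


def _canonical(a: str, b: str, rel: str, network: RegulatoryNetwork) -> tuple[str, str]:
    # mt edges read miRNA -> gene; pp edges are sorted lexicographically
    if rel == RELATION_MIRNA_TARGET and network.kind(b) == "mirna":
        return b, a
    if rel == RELATION_PPI and b < a:
        return b, a
    return a, b


def _write_node_attrs(network: RegulatoryNetwork, path: Path) -> None:
    lines = ["node_id\tkind\tdirection\tdegree\tppi_degree"]
    for n in sorted(network.graph.nodes):
        data = network.graph.nodes[n]
        lines.append(
            f"{n}\t{data.get('kind')}\t{data.get('direction') or ''}"
            f"\t{network.degree(n)}\t{network.ppi_degree(n)}"
        )
    path.write_text("\n".join(lines) + "\n")


def import_graphml(path) -> RegulatoryNetwork:
    """Read back a network exported as GraphML; round-trips exactly."""
    g = nx.read_graphml(path)
    net = RegulatoryNetwork()
    for n, data in g.nodes(data=True):
        direction = data.get("direction") or None
        if data.get("kind") == "mirna":
            net.add_mirna(n, direction)
        else:
            net.add_protein(n, direction)
    for a, b, data in g.edges(data=True):
        if data.get("relation") == RELATION_MIRNA_TARGET:
            mirna, gene = (a, b) if net.kind(a) == "mirna" else (b, a)
            net.add_regulatory_edge(mirna, gene)
        else:
            net.add_ppi_edge(a, b)
    return net
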