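"""Heterogeneous network assembly.

The network has two node types — lncRNA ("L") and protein ("P") — and three
undirected edge types: LL_sim (thresholded lncRNA-lncRNA similarity), PP_sim
(thresholded protein-protein similarity) and LP_interact (known interactions).
Similarity edges survive only if the pair's Jaccard index exceeds a type
threshold *and* its BLAST e-value is present and below a type threshold:
Jaccard > 0.5 with e-value < 0.001 on the lncRNA side and Jaccard > 0 with
e-value < 0.01 on the protein side, both comparisons strict.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .io_formats import InteractionList
from .similarity import SimilarityTable

EDGE_TYPES = ("LL_sim", "PP_sim", "LP_interact")

_ENDPOINTS = {"LL_sim": ("L", "L"), "PP_sim": ("P", "P"), "LP_interact": ("L", "P")}


class NodeTypeConflictError(ValueError):
    """An id was used both as a lncRNA and as a protein."""


@dataclass
class HeteroNetwork:
    """Undirected typed graph backed by a :class:`networkx.Graph`.

    Node attribute ``ntype`` in {"L", "P"}; edge attribute ``etype`` in
    ``EDGE_TYPES``. Endpoint types are enforced on insertion.
    """

    graph: nx.Graph

    def __init__(self) -> None:
        self.graph = nx.Graph()

    def add_node(self, node_id: str, ntype: str) -> None:
        if ntype not in ("L", "P"):
            raise ValueError(f"unknown node type {ntype!r}")
        existing = self.graph.nodes.get(node_id)
        if existing is not None and existing["ntype"] != ntype:
            raise NodeTypeConflictError(
                f"id {node_id!r} used as both {existing['ntype']} and {ntype}"
            )
        self.graph.add_node(node_id, ntype=ntype)

    def add_edge(self, a: str, b: str, etype: str) -> None:
        if etype not in EDGE_TYPES:
            raise ValueError(f"unknown edge type {etype!r}")
        if a == b:
            raise ValueError(f"self-loop on {a!r}")
        want = _ENDPOINTS[etype]
        ta, tb = self.node_type(a), self.node_type(b)
        if {ta, tb} != set(want) or sorted((ta, tb)) != sorted(want):
            raise ValueError(
                f"edge type {etype} cannot join {ta} node {a!r} and {tb} node {b!r}"
            )
        self.graph.add_edge(a, b, etype=etype)

    def node_type(self, node_id: str) -> str:
        try:
            return self.graph.nodes[node_id]["ntype"]
        except KeyError:
            raise KeyError(f"unknown node id {node_id!r}")

    def nodes(self, ntype: str | None = None) -> list[str]:
        if ntype is None:
            return sorted(self.graph.nodes)
        return sorted(n for n, d in self.graph.nodes(data=True) if d["ntype"] == ntype)

    def neighbors(self, node_id: str) -> list[str]:
        return sorted(self.graph.neighbors(node_id))

    def edges(self) -> set[tuple[str, str, str]]:
        return {
            (min(a, b), max(a, b), d["etype"])
            for a, b, d in self.graph.edges(data=True)
        }

    def edge_type_counts(self) -> dict[str, int]:
        counts = {t: 0 for t in EDGE_TYPES}
        for _, _, d in self.graph.edges(data=True):
            counts[d["etype"]] += 1
        return counts

    def present_edge_types(self) -> set[tuple[str, str]]:
        """Node-type pairs realizable as single edges in this network,
        as sorted tuples, e.g. {("L", "L"), ("L", "P")}."""
        return {
            tuple(sorted(_ENDPOINTS[d["etype"]]))
            for _, _, d in self.graph.edges(data=True)
        }

    @property
    def num_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def num_edges(self) -> int:
        return self.graph.number_of_edges()

    def is_connected(self) -> bool:
        return nx.is_connected(self.graph)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for a, b, etype in sorted(self.edges()):
                fh.write(f"{a}\t{b}\t{etype}\n")


@dataclass(frozen=True)
class EdgeFilter:
    """Similarity-edge selection rule: keep a pair iff its Jaccard index
    beats ``jaccard_min`` (strictly, by default) and a BLAST e-value is
    present and strictly below ``evalue_max``."""

    jaccard_min: float
    evalue_max: float
    jaccard_strict: bool = True

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")

    def keeps(self, jaccard: float, evalue: float | None) -> bool:
        if evalue is None or not evalue < self.evalue_max:
            return False
        if self.jaccard_strict:
            return jaccard > self.jaccard_min
        return jaccard >= self.jaccard_min


# default per-type selection rules
LNCRNA_FILTER = EdgeFilter(jaccard_min=0.5, evalue_max=0.001)
PROTEIN_FILTER = EdgeFilter(jaccard_min=0.0, evalue_max=0.01)


def filter_similarity_edges(
    table: SimilarityTable, f: EdgeFilter
) -> set[tuple[str, str]]:
    """Unordered id pairs passing the filter. An absent e-value fails the
    filter: no BLAST evidence is not the same as e-value 0."""
    return {
        pair for pair, (j, ev) in table.entries.items() if f.keeps(j, ev)
    }


def build_network(
    l_edges: set[tuple[str, str]],
    p_edges: set[tuple[str, str]],
    interactions: InteractionList,
    l_nodes: list[str] | None = None,
    p_nodes: list[str] | None = None,
) -> tuple[HeteroNetwork, dict[str, int]]:
    """Union of the two similarity networks and the known interactions.

    ``l_nodes`` / ``p_nodes`` list every sequence id so that nodes left
    isolated by the filters are still present (walks simply never start
    there, but they keep an embedding row). Returns the network and the
    per-edge-type counts.
    """
    net = HeteroNetwork()
    for node in l_nodes or []:
        net.add_node(node, "L")
    for node in p_nodes or []:
        net.add_node(node, "P")
    for a, b in sorted(l_edges):
        net.add_node(a, "L")
        net.add_node(b, "L")
        net.add_edge(a, b, "LL_sim")
    for a, b in sorted(p_edges):
        net.add_node(a, "P")
        net.add_node(b, "P")
        net.add_edge(a, b, "PP_sim")
    for l, p in sorted(interactions.pairs):
        net.add_node(l, "L")
        net.add_node(p, "P")
        net.add_edge(l, p, "LP_interact")
    return net, net.edge_type_counts()


def toy_network() -> HeteroNetwork:
    """The six-node worked-example network: four lncRNAs L1..L4, two
    proteins P1, P2, no protein-protein edges.

    This fixture encodes the minimal connected edge set with the defining
    property that the relations from L1 to P1 within two steps are exactly
    {L-P, L-L-P}:
    L1-P1 and L1-L2-P1 are the only short L1->P1 routes, and the L3/L4/P2
    block attaches via L2-L3 without creating new ones.
    """
    net = HeteroNetwork()
    for l in ("L1", "L2", "L3", "L4"):
        net.add_node(l, "L")
    for p in ("P1", "P2"):
        net.add_node(p, "P")
    net.add_edge("L1", "P1", "LP_interact")
    net.add_edge("L1", "L2", "LL_sim")
    net.add_edge("L2", "P1", "LP_interact")
    net.add_edge("L2", "L3", "LL_sim")
    net.add_edge("L3", "L4", "LL_sim")
    net.add_edge("L3", "P2", "LP_interact")
    net.add_edge("L4", "P2", "LP_interact")
    return net
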