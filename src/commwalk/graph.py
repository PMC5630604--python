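"""Modular community graph underlying all stimulus sequences.

The default graph has 15 nodes arranged in three 5-node communities.  Each
community is a 5-clique minus the edge between its two *boundary* nodes, and
the boundary nodes carry one bridge edge each to a boundary node of the
adjacent community, with communities arranged in a ring.  This is the unique
simple construction in which every node has degree 4, there are 30 edges, and
removing the 3 bridges leaves three 5-cliques-minus-an-edge.

Node ids are contiguous per community ([0-4], [5-9], [10-14] by default) and
the boundary nodes of a community are the first and last id of its block.
Because every node has the same degree, a random walk on this graph has
uniform pairwise transition probabilities (1/4), so community structure is
carried entirely by higher-order sequence statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "CommunityGraph",
    "InvalidGraphConfig",
    "build_community_graph",
    "transition_matrix",
    "validate_graph",
    "GraphValidationReport",
    "graph_to_json",
    "graph_from_json",
    "write_edge_list",
    "read_edge_list",
]


class InvalidGraphConfig(ValueError):
    """Raised when requested parameters cannot satisfy the construction."""


class CommunityGraph:
    """A simple undirected graph with a community label per node.

    Attributes
    ----------
    graph : networkx.Graph
        The underlying simple graph.
    community_of : dict[int, int]
        Node id -> community index.
    n_communities, community_size : int
        Parameters of the builder (recorded for validation).
    """

    def __init__(self, graph: nx.Graph, community_of: dict[int, int],
                 n_communities: int, community_size: int):
        self.graph = graph
        self.community_of = dict(community_of)
        self.n_communities = int(n_communities)
        self.community_size = int(community_size)
        # sorted neighbour lists give deterministic iteration everywhere
        self._neighbors = {u: tuple(sorted(graph.neighbors(u)))
                           for u in sorted(graph.nodes)}
        self._ham_cache: dict[int, tuple[tuple[int, ...], ...]] = {}

    # -- basic accessors -------------------------------------------------
    @property
    def node_ids(self) -> list[int]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def edges(self) -> list[tuple[int, int]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    def neighbors(self, u: int) -> tuple[int, ...]:
        return self._neighbors[u]

    def degree(self, u: int) -> int:
        return len(self._neighbors[u])

    def has_edge(self, u: int, v: int) -> bool:
        return self.graph.has_edge(u, v)

    def is_bridge_edge(self, u: int, v: int) -> bool:
        return self.community_of[u] != self.community_of[v]

    @property
    def bridge_edges(self) -> list[tuple[int, int]]:
        return [e for e in self.edges if self.is_bridge_edge(*e)]

    def is_boundary(self, u: int) -> bool:
        """A node is a boundary node if it touches a cross-community edge."""
        return any(self.community_of[v] != self.community_of[u]
                   for v in self._neighbors[u])

    @property
    def boundary_nodes(self) -> list[int]:
        return [u for u in self.node_ids if self.is_boundary(u)]

    def community_labels(self) -> np.ndarray:
        """Community index per node id, as an array indexable by node id."""
        lab = np.empty(max(self.node_ids) + 1, dtype=int)
        for u, c in self.community_of.items():
            lab[u] = c
        return lab

    def __eq__(self, other) -> bool:
        return (isinstance(other, CommunityGraph)
                and self.edges == other.edges
                and self.community_of == other.community_of)

    def __repr__(self) -> str:
        return (f"CommunityGraph(n_nodes={self.n_nodes}, "
                f"n_edges={self.graph.number_of_edges()}, "
                f"n_communities={self.n_communities})")


def build_community_graph(n_communities: int = 3,
                          community_size: int = 5) -> CommunityGraph:
    """Build the ring-of-cliques community graph.

    Each community is a clique on ``community_size`` nodes minus the edge
    between its two boundary nodes; each boundary node carries exactly one
    bridge to a boundary node of the adjacent community in the ring.  The
    result is (community_size - 1)-regular.

    Raises
    ------
    InvalidGraphConfig
        If ``n_communities < 3`` (a ring of communities is undefined) or
        ``community_size < 3`` (removing the boundary pair edge would
        disconnect the community).
    """
    if n_communities < 3:
        raise InvalidGraphConfig(
            f"need at least 3 communities for a ring, got {n_communities}")
    if community_size < 3:
        raise InvalidGraphConfig(
            f"need community_size >= 3, got {community_size}")

    g = nx.Graph()
    community_of: dict[int, int] = {}
    m = community_size
    for c in range(n_communities):
        block = list(range(c * m, (c + 1) * m))
        for u in block:
            community_of[u] = c
        first, last = block[0], block[-1]
        for i, u in enumerate(block):
            for v in block[i + 1:]:
                if {u, v} == {first, last}:
                    continue  # boundary pair stays unconnected
                g.add_edge(u, v)
    # bridges: last node of community c -> first node of community c+1
    for c in range(n_communities):
        u = c * m + (m - 1)
        v = ((c + 1) % n_communities) * m
        g.add_edge(u, v)
    return CommunityGraph(g, community_of, n_communities, community_size)


def transition_matrix(graph: CommunityGraph) -> np.ndarray:
    """Row-stochastic matrix of the unbiased random walk on ``graph``.

    Entry (i, j) is 1/degree(i) when {i, j} is an edge, else 0.  On the
    default 4-regular graph every nonzero entry equals 0.25.
    """
    n = max(graph.node_ids) + 1
    tm = np.zeros((n, n))
    for u in graph.node_ids:
        for v in graph.neighbors(u):
            tm[u, v] = 1.0 / graph.degree(u)
    return tm


@dataclass
class GraphValidationReport:
    """Outcome of the structural checks on a CommunityGraph."""

    degree_distribution: dict[int, int]
    n_edges: int
    community_sizes: dict[int, int]
    n_bridges: int
    connected: bool
    checks: dict[str, bool] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return all(self.checks.values())

    def failed(self) -> list[str]:
        return [k for k, v in self.checks.items() if not v]

    def to_dict(self) -> dict:
        return {
            "degree_distribution": self.degree_distribution,
            "n_edges": self.n_edges,
            "community_sizes": self.community_sizes,
            "n_bridges": self.n_bridges,
            "connected": self.connected,
            "checks": dict(self.checks),
            "ok": self.ok,
        }


def validate_graph(graph: CommunityGraph) -> GraphValidationReport:
    """Report-only validation of every structural invariant.

    Checks degree regularity, edge count, community sizes, bridge count,
    absence of self loops, connectivity, and that removing the bridges
    yields one component per community.
    """
    g = graph.graph
    m, k = graph.community_size, graph.n_communities
    degrees = dict(g.degree())
    degree_dist: dict[int, int] = {}
    for d in degrees.values():
        degree_dist[d] = degree_dist.get(d, 0) + 1

    comm_sizes: dict[int, int] = {}
    for c in graph.community_of.values():
        comm_sizes[c] = comm_sizes.get(c, 0) + 1

    bridges = graph.bridge_edges
    connected = nx.is_connected(g) if g.number_of_nodes() else False

    stripped = g.copy()
    stripped.remove_edges_from(bridges)
    comps = list(nx.connected_components(stripped))

    expected_degree = m - 1
    checks = {
        "degree_regular": all(d == expected_degree for d in degrees.values()),
        "edge_count": g.number_of_edges() == k * (m * (m - 1) // 2 - 1) + k,
        "community_sizes": all(s == m for s in comm_sizes.values())
                           and len(comm_sizes) == k,
        "bridge_count": len(bridges) == k,
        "no_self_loops": nx.number_of_selfloops(g) == 0,
        "connected": connected,
        "bridges_separate_communities": (
            len(comps) == k and all(len(cc) == m for cc in comps)),
    }
    return GraphValidationReport(
        degree_distribution=degree_dist,
        n_edges=g.number_of_edges(),
        community_sizes=comm_sizes,
        n_bridges=len(bridges),
        connected=connected,
        checks=checks,
    )


# -- serialization -------------------------------------------------------

def graph_to_json(graph: CommunityGraph) -> str:
    doc = {
        "n_communities": graph.n_communities,
        "community_size": graph.community_size,
        "edges": graph.edges,
        "community_of": {str(u): c for u, c in graph.community_of.items()},
    }
    return json.dumps(doc, indent=1)


def graph_from_json(text: str) -> CommunityGraph:
    doc = json.loads(text)
    g = nx.Graph()
    g.add_nodes_from(int(u) for u in doc["community_of"])
    g.add_edges_from((int(u), int(v)) for u, v in doc["edges"])
    community_of = {int(u): int(c) for u, c in doc["community_of"].items()}
    return CommunityGraph(g, community_of,
                          doc["n_communities"], doc["community_size"])


def write_edge_list(graph: CommunityGraph, edge_path: str | Path,
                    community_path: str | Path | None = None) -> None:
    """Plain 'u v' edge list plus a JSON sidecar mapping node -> community."""
    edge_path = Path(edge_path)
    lines = [f"{u} {v}" for u, v in graph.edges]
    edge_path.write_text("\n".join(lines) + "\n")
    if community_path is None:
        community_path = edge_path.with_suffix(".communities.json")
    Path(community_path).write_text(json.dumps(
        {str(u): c for u, c in graph.community_of.items()}, indent=1))


def read_edge_list(edge_path: str | Path,
                   community_path: str | Path) -> CommunityGraph:
    g = nx.Graph()
    for line in Path(edge_path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        u, v = line.split()
        g.add_edge(int(u), int(v))
    community_of = {int(u): int(c) for u, c in
                    json.loads(Path(community_path).read_text()).items()}
    g.add_nodes_from(community_of)
    n_comm = len(set(community_of.values()))
    size = len(community_of) // max(n_comm, 1)
    return CommunityGraph(g, community_of, n_comm, size)
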