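"""Exposure-sequence generators and their diagnostic statistics.

Three walk regimes on the community graph:

* ``random`` — an unbiased random walk (uniform over the 4 neighbours at
  every step), the default exposure length being 1400 trials.
* ``hamiltonian`` — a concatenation of randomly selected forward and
  backward Hamiltonian paths; each path presents all 15 nodes exactly once,
  and each new path starts at a uniformly drawn neighbour of the previous
  terminal node (93 paths -> 1395 trials by default).
* ``eulerian`` — a concatenation of random Eulerian circuits, each
  traversing all 30 edges exactly once, truncated to 1395 trials.  Circuits
  are generated with a randomized Hierholzer construction; because every
  node has even degree the circuits are closed, and the shared junction
  node between consecutive circuits is emitted once so the sequence stays
  continuous with no immediate repeats.

Hamiltonian paths are sampled uniformly from the exhaustive backtracking
enumeration from the required start node.  Since reversing a path that ends
at *s* yields a path that starts at *s*, the enumeration from *s* is already
closed under reversal, which is how "forward and backward" paths enter the
candidate set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .graph import CommunityGraph

__all__ = [
    "WalkSequence",
    "WalkGenerationError",
    "random_walk",
    "enumerate_hamiltonian_paths",
    "hamiltonian_sequence",
    "random_eulerian_circuit",
    "eulerian_sequence",
    "empirical_transition_probabilities",
    "community_run_lengths",
    "next_step_uncertainty_profile",
]

CONDITIONS = ("random", "eulerian", "hamiltonian")


class WalkGenerationError(RuntimeError):
    """Raised when a sequence cannot be generated (e.g. no Eulerian circuit)."""


@dataclass
class WalkSequence:
    """An ordered node sequence with its constituent-path bookkeeping.

    ``path_starts`` holds the index at which each constituent path begins
    (``[0]`` for a random walk).  For the Eulerian condition consecutive
    circuits share their junction node, so circuit *k* occupies indices
    ``path_starts[k] .. path_starts[k] + 30`` inclusive.
    """

    condition: str
    nodes: np.ndarray
    path_starts: list[int] = field(default_factory=lambda: [0])
    seed: int | None = None

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=int)

    def __len__(self) -> int:
        return len(self.nodes)

    def path_index(self) -> np.ndarray:
        """Constituent-path index per trial (0-based)."""
        starts = np.asarray(self.path_starts)
        return np.maximum(np.searchsorted(starts, np.arange(len(self)),
                                          side="right") - 1, 0)

    def within_path_position(self) -> np.ndarray:
        """1-based position of each trial within its constituent path."""
        starts = np.asarray(self.path_starts)
        return np.arange(len(self)) - starts[self.path_index()] + 1


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _nodes_of(walk) -> np.ndarray:
    if isinstance(walk, WalkSequence):
        return walk.nodes
    return np.asarray(walk, dtype=int)


# -- random walk ----------------------------------------------------------

def random_walk(graph: CommunityGraph, length: int,
                seed: int | np.random.Generator | None = None) -> WalkSequence:
    """Unbiased random walk: uniform start, uniform successor among neighbours."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = _as_rng(seed)
    nodes = np.empty(length, dtype=int)
    current = int(rng.choice(graph.node_ids))
    nodes[0] = current
    for t in range(1, length):
        nbrs = graph.neighbors(current)
        current = nbrs[rng.integers(len(nbrs))]
        nodes[t] = current
    return WalkSequence("random", nodes, [0],
                        seed if isinstance(seed, int) else None)


# -- Hamiltonian condition -------------------------------------------------

def enumerate_hamiltonian_paths(graph: CommunityGraph,
                                start: int) -> list[tuple[int, ...]]:
    """All simple paths from ``start`` visiting every node exactly once.

    Exhaustive backtracking in lexicographic neighbour order; the result is
    deterministic and cached per graph, and serves as the sampling pool and
    as the correctness oracle for the Hamiltonian generator.
    """
    if start not in graph.community_of:
        raise ValueError(f"unknown start node {start}")
    if start in graph._ham_cache:
        return list(graph._ham_cache[start])
    n = graph.n_nodes
    paths: list[tuple[int, ...]] = []
    visited = {start}
    path = [start]

    def extend(u: int) -> None:
        if len(path) == n:
            paths.append(tuple(path))
            return
        for v in graph.neighbors(u):
            if v not in visited:
                visited.add(v)
                path.append(v)
                extend(v)
                path.pop()
                visited.remove(v)

    extend(start)
    graph._ham_cache[start] = tuple(paths)
    return paths


def hamiltonian_sequence(graph: CommunityGraph, n_paths: int,
                         seed: int | np.random.Generator | None = None
                         ) -> WalkSequence:
    """Concatenate ``n_paths`` uniformly sampled Hamiltonian paths.

    The first path starts at a uniformly drawn node; every subsequent path
    starts at a uniformly drawn neighbour of the previous terminal node, so
    the junction pairs are edges and the sequence is continuous.  Total
    length is ``n_nodes * n_paths`` (15 x 93 = 1395 by default).
    """
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    rng = _as_rng(seed)
    nodes: list[int] = []
    path_starts: list[int] = []
    terminal: int | None = None
    for _ in range(n_paths):
        if terminal is None:
            candidates = list(graph.node_ids)
        else:
            candidates = list(graph.neighbors(terminal))
        path = None
        while candidates:
            i = rng.integers(len(candidates))
            start = candidates.pop(int(i))
            pool = enumerate_hamiltonian_paths(graph, start)
            if pool:
                path = pool[rng.integers(len(pool))]
                break
        if path is None:
            raise WalkGenerationError(
                "no Hamiltonian path from any admissible start node")
        path_starts.append(len(nodes))
        nodes.extend(path)
        terminal = path[-1]
    return WalkSequence("hamiltonian", np.array(nodes), path_starts,
                        seed if isinstance(seed, int) else None)


# -- Eulerian condition -----------------------------------------------------

def _adjacency_copy(graph: CommunityGraph) -> dict[int, list[int]]:
    return {u: list(graph.neighbors(u)) for u in graph.node_ids}


def random_eulerian_circuit(graph: CommunityGraph, start: int,
                            seed: int | np.random.Generator | None = None
                            ) -> list[int]:
    """Random closed trail covering every edge exactly once.

    Randomized Hierholzer construction: walk random unused edges until stuck
    (necessarily back at the start because all degrees are even), implicitly
    splicing sub-circuits via the stack.  Returns 31 nodes / 30 edge
    traversals on the default graph, with first node == last node.
    """
    odd = [u for u in graph.node_ids if graph.degree(u) % 2]
    if odd:
        raise WalkGenerationError(
            f"no Eulerian circuit: odd-degree nodes {odd}")
    rng = _as_rng(seed)
    adj = _adjacency_copy(graph)
    stack = [start]
    trail: list[int] = []
    while stack:
        v = stack[-1]
        if adj[v]:
            u = adj[v].pop(rng.integers(len(adj[v])))
            adj[u].remove(v)
            stack.append(u)
        else:
            trail.append(stack.pop())
    trail.reverse()
    return trail


def eulerian_sequence(graph: CommunityGraph, total_length: int,
                      seed: int | np.random.Generator | None = None
                      ) -> WalkSequence:
    """Concatenated random Eulerian circuits truncated at ``total_length``.

    Each circuit starts at the previous circuit's terminal node (its own
    start, since circuits are closed); the duplicated junction node is
    emitted once, so consecutive trials are always edges and nothing repeats
    immediately.
    """
    if total_length < 1:
        raise ValueError("total_length must be >= 1")
    rng = _as_rng(seed)
    nodes: list[int] = []
    path_starts: list[int] = []
    start = int(rng.choice(graph.node_ids))
    while len(nodes) < total_length:
        circuit = random_eulerian_circuit(graph, start, rng)
        if not nodes:
            path_starts.append(0)
            nodes.extend(circuit)
        else:
            path_starts.append(len(nodes) - 1)  # shared junction node
            nodes.extend(circuit[1:])
        start = circuit[-1]
    nodes = nodes[:total_length]
    path_starts = [p for p in path_starts if p < total_length]
    return WalkSequence("eulerian", np.array(nodes), path_starts,
                        seed if isinstance(seed, int) else None)


# -- diagnostics ------------------------------------------------------------

def empirical_transition_probabilities(walk, graph: CommunityGraph
                                       ) -> tuple[np.ndarray, np.ndarray]:
    """Bigram counts and row-normalized transition frequencies of a walk.

    Returns ``(probabilities, counts)``; rows with no outgoing transitions
    are left at zero.  Accepts a WalkSequence or a raw node array.
    """
    nodes = _nodes_of(walk)
    if len(nodes) == 0:
        raise ValueError("walk is empty")
    n = max(graph.node_ids) + 1
    counts = np.zeros((n, n), dtype=int)
    if len(nodes) > 1:
        np.add.at(counts, (nodes[:-1], nodes[1:]), 1)
    row = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(row > 0, counts / np.maximum(row, 1), 0.0)
    return probs, counts


def community_run_lengths(walk, graph: CommunityGraph) -> list[int]:
    """Lengths of maximal runs of consecutive same-community trials."""
    nodes = _nodes_of(walk)
    if len(nodes) == 0:
        raise ValueError("walk is empty")
    comm = graph.community_labels()[nodes]
    change = np.flatnonzero(np.diff(comm)) + 1
    bounds = np.concatenate(([0], change, [len(comm)]))
    return list(np.diff(bounds))


def _entropy_bits(probabilities: np.ndarray) -> float:
    p = probabilities[probabilities > 0]
    return float(-(p * np.log2(p)).sum())


def _feasible_next_nodes(graph: CommunityGraph, adj: dict[int, list[int]],
                         current: int, start: int) -> list[int]:
    """Unused incident edges whose traversal keeps the circuit completable.

    After tentatively consuming (current, u), an Eulerian trail from u back
    to ``start`` over the remaining edges exists iff every remaining edge is
    reachable from u (degree parity is automatic along a partial circuit).
    """
    feasible = []
    for u in list(adj[current]):
        adj[current].remove(u)
        adj[u].remove(current)
        remaining = {v for v, nb in adj.items() if nb}
        if not remaining:
            ok = u == start
        else:
            # BFS over nodes that still have unused edges, from u
            seen = {u}
            frontier = [u]
            while frontier:
                v = frontier.pop()
                for w in adj[v]:
                    if w not in seen:
                        seen.add(w)
                        frontier.append(w)
            ok = remaining <= seen
        adj[current].append(u)
        adj[u].append(current)
        if ok:
            feasible.append(u)
    return feasible


def next_step_uncertainty_profile(graph: CommunityGraph, condition: str,
                                  n_samples: int = 100,
                                  seed: int | np.random.Generator | None = None
                                  ) -> np.ndarray:
    """Mean Shannon entropy (bits) of the next node at each within-path position.

    For the Hamiltonian condition the ensemble is the exact enumeration of
    admissible paths sharing the observed prefix (uniform over paths); the
    profile has one entry per predictable position (14 on the default
    graph) and is non-increasing in expectation, reaching 0 once the prefix
    pins down the path.  For the Eulerian condition the ensemble is the
    feasibility-constrained random-successor process over unused edges (30
    positions).  For the random walk the entropy is a constant
    log2(degree) = 2 bits at every position; it is returned over one
    nominal 15-node path for comparison plots.
    """
    rng = _as_rng(seed)
    if condition == "random":
        deg = graph.community_size - 1
        return np.full(graph.n_nodes - 1, math.log2(deg))
    if condition == "hamiltonian":
        n_pos = graph.n_nodes - 1
        acc = np.zeros(n_pos)
        for _ in range(n_samples):
            start = int(rng.choice(graph.node_ids))
            pool = enumerate_hamiltonian_paths(graph, start)
            path = pool[rng.integers(len(pool))]
            live = pool
            for k in range(n_pos):
                live = [p for p in live if p[k] == path[k]]
                nxt: dict[int, int] = {}
                for p in live:
                    nxt[p[k + 1]] = nxt.get(p[k + 1], 0) + 1
                probs = np.array(list(nxt.values()), dtype=float)
                acc[k] += _entropy_bits(probs / probs.sum())
        return acc / n_samples
    if condition == "eulerian":
        n_pos = graph.graph.number_of_edges()
        acc = np.zeros(n_pos)
        for _ in range(n_samples):
            start = int(rng.choice(graph.node_ids))
            adj = _adjacency_copy(graph)
            current = start
            for k in range(n_pos):
                feasible = _feasible_next_nodes(graph, adj, current, start)
                acc[k] += math.log2(len(feasible))
                u = feasible[rng.integers(len(feasible))]
                adj[current].remove(u)
                adj[u].remove(current)
                current = u
        return acc / n_samples
    raise ValueError(f"unknown condition {condition!r}")
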