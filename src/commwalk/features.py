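"""Per-trial analysis covariates derived from a walk.

Three derived quantities drive the analysis:

* ``node_type`` — a trial is a *transition* when the sequence enters a new
  community, except that when a bridge edge is immediately re-traversed
  backwards (the a-b-a pattern across a community boundary, e.g. 5-6-5) only
  the first crossing is counted.  The trial immediately before a counted
  transition is a *pre-transition*; everything else is *other*.  When a
  single trial would be both (a community run of length 1), transition takes
  precedence so the factor levels stay disjoint.
* ``lag10`` — how many times the current node appeared among the previous
  10 trials (window clipped at the sequence start).
* ``recency`` — trials elapsed since the current node last appeared; NaN at
  a node's first occurrence (an immediate repeat is impossible on a simple
  graph, so recency is never 0 under the default convention).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .graph import CommunityGraph
from .walks import WalkSequence, _nodes_of

__all__ = [
    "label_node_types",
    "compute_lag10",
    "compute_recency",
    "assemble_trial_features",
]

NODE_TYPES = ("other", "pre_transition", "transition")


def label_node_types(walk, graph: CommunityGraph) -> np.ndarray:
    """Label each trial as transition / pre_transition / other.

    Trial t is a transition iff its community differs from trial t-1's,
    unless the walk is re-traversing the same bridge edge backwards
    (nodes[t] == nodes[t-2] with a counted transition at t-1), in which case
    only the first crossing counts.  Trial 1 is never a transition.
    """
    nodes = _nodes_of(walk)
    if len(nodes) == 0:
        raise ValueError("walk is empty")
    comm = graph.community_labels()[nodes]
    n = len(nodes)
    is_transition = np.zeros(n, dtype=bool)
    for t in np.flatnonzero(comm[1:] != comm[:-1]) + 1:
        if t >= 2 and nodes[t] == nodes[t - 2] and is_transition[t - 1]:
            continue  # backward re-traversal of the same bridge: not counted
        is_transition[t] = True
    labels = np.full(n, "other", dtype=object)
    is_pre = np.zeros(n, dtype=bool)
    is_pre[:-1] = is_transition[1:]
    is_pre &= ~is_transition  # transition takes precedence on collision
    labels[is_pre] = "pre_transition"
    labels[is_transition] = "transition"
    return labels


def compute_lag10(walk, window: int = 10) -> np.ndarray:
    """Occurrences of the current node among the previous ``window`` trials."""
    nodes = _nodes_of(walk)
    if len(nodes) == 0:
        raise ValueError("walk is empty")
    n = len(nodes)
    counts = np.zeros(n, dtype=int)
    for k in range(1, min(window, n - 1) + 1):
        counts[k:] += nodes[k:] == nodes[:-k]
    return counts


def compute_recency(walk, convention: str = "elapsed") -> np.ndarray:
    """Trials elapsed since the current node's most recent prior occurrence.

    NaN marks first occurrences.  ``convention='elapsed'`` (default) counts
    trial indices inclusively (t - t_last, so an x-y-x return scores 2);
    ``convention='exclusive'`` counts the strictly intervening trials
    (t - t_last - 1), an alternative indexing under which a return after one
    intervening trial scores 1 and a hypothetical immediate repeat would
    score 0.
    """
    if convention not in ("elapsed", "exclusive"):
        raise ValueError(f"unknown recency convention {convention!r}")
    nodes = _nodes_of(walk)
    if len(nodes) == 0:
        raise ValueError("walk is empty")
    idx = pd.Series(np.arange(len(nodes), dtype=float))
    last = idx.groupby(nodes).shift(1)
    rec = (idx - last).to_numpy()
    if convention == "exclusive":
        rec = rec - 1.0
    return rec


def assemble_trial_features(walk: WalkSequence,
                            graph: CommunityGraph) -> pd.DataFrame:
    """One row per trial: node identity, community, node type, priming covariates.

    Columns: trial (1-based), node_id, community, node_type, lag10, recency,
    path_index (0-based constituent path), within_path_position (1-based).
    """
    nodes = walk.nodes
    bad = set(np.unique(nodes)) - set(graph.node_ids)
    if bad:
        raise ValueError(f"walk contains nodes absent from the graph: {sorted(bad)}")
    comm = graph.community_labels()[nodes]
    return pd.DataFrame({
        "trial": np.arange(1, len(nodes) + 1),
        "node_id": nodes,
        "community": comm,
        "node_type": label_node_types(walk, graph),
        "lag10": compute_lag10(walk),
        "recency": compute_recency(walk),
        "path_index": walk.path_index(),
        "within_path_position": walk.within_path_position(),
    })
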