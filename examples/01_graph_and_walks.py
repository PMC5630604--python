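"""Build the modular graph and generate the three exposure-sequence regimes.

The graph has 15 nodes in three 5-node communities; every node has degree 4,
so a random walk has uniform 1/4 transition probabilities and community
structure is visible only in higher-order sequence statistics.
"""

import numpy as np

from commwalk import (build_community_graph, community_run_lengths,
                      empirical_transition_probabilities, eulerian_sequence,
                      hamiltonian_sequence, random_walk,
                      transition_matrix, validate_graph)

graph = build_community_graph()
report = validate_graph(graph)
print("graph checks pass:", report.ok)
print("degree distribution:", report.degree_distribution,
      "| edges:", report.n_edges, "| bridges:", report.n_bridges)

tm = transition_matrix(graph)
print("distinct nonzero transition probabilities:",
      sorted(set(np.round(tm[tm > 0], 6))))

walks = {
    "random": random_walk(graph, 1400, seed=0),
    "eulerian": eulerian_sequence(graph, 1395, seed=0),
    "hamiltonian": hamiltonian_sequence(graph, 93, seed=0),
}
for name, walk in walks.items():
    runs = community_run_lengths(walk, graph)
    probs, counts = empirical_transition_probabilities(walk, graph)
    print(f"{name:12s} length {len(walk):4d} | constituent paths "
          f"{len(walk.path_starts):3d} | mean community run "
          f"{np.mean(runs):5.2f} trials")

# Random and Eulerian walks dwell inside communities (long runs); the
# Hamiltonian walk sweeps all 15 nodes per path and moves between
# communities every ~5 trials, which is the redundancy contrast the three
# regimes are designed to create.

from commwalk import next_step_uncertainty_profile

print("\nnext-step uncertainty (bits) by within-path position:")
for condition in ("random", "hamiltonian"):
    prof = next_step_uncertainty_profile(graph, condition, n_samples=150,
                                         seed=1)
    head = " ".join(f"{x:4.2f}" for x in prof[:8])
    print(f"{condition:12s} {head} ...  (final position: {prof[-1]:.2f})")
# The random walk stays at 2 bits everywhere; structured walks sample from a
# shrinking admissible set, so uncertainty collapses within each community
# block and vanishes once the path is fully determined.
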