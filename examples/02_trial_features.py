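"""Derive per-trial covariates: node types and repetition-priming predictors.

Reproduces the worked 11-trial example: viewing 1-2-5-4-3-5-3-1-3-2-5, the
final node (5) was seen twice in the previous 10 trials (Lag10 = 2) and last
seen 5 trials earlier (Recency = 5).
"""

import numpy as np

from commwalk import (assemble_trial_features, build_community_graph,
                      compute_lag10, compute_recency, label_node_types)
from commwalk.walks import WalkSequence

sequence = [1, 2, 5, 4, 3, 5, 3, 1, 3, 2, 5]
print("sequence:", "-".join(map(str, sequence)))
print("final-trial Lag10:  ", compute_lag10(sequence)[-1])
print("final-trial Recency:", compute_recency(sequence)[-1])

# node-type labels on a walk that enters community 1 and bounces back:
# the 4-5-4 pattern counts only the first crossing (entry at node 5)
graph = build_community_graph()
walk = np.array([3, 4, 5, 4, 3, 2])
labels = label_node_types(walk, graph)
for node, label in zip(walk, labels):
    print(f"  node {node:2d} -> {label}")

# the full feature table joins everything the models consume
table = assemble_trial_features(
    WalkSequence("random", np.array(sequence)), graph)
print(table.tail(3).to_string(index=False))
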