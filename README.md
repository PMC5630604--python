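# commwalk

Community-structured graph walks, synthetic reaction-time streams, and
mixed-effects surprisal analysis.

`commwalk` is a research library for studying how the *temporal organization*
of a stimulus sequence — the walk used to traverse a graph — shapes a
learner's sensitivity to the graph's community structure. It targets
cognitive/network scientists who want a fully reproducible, testable stand-in
for the classic visual statistical-learning paradigm: participants watch a
continuous stream of images generated by a walk on a modular graph while
performing an orientation cover task, and their reaction times reveal
whether they anticipate community boundaries.

## What it implements

**Graph.** A 15-node graph with three 5-node communities: each community is
a 5-clique minus the edge between its two boundary nodes, and three bridge
edges join the communities in a ring. Every node has degree 4, so a random
walk has uniform pairwise transition probabilities (1/4) and community
structure is carried only by higher-order statistics.

**Walks.** Three exposure regimes on that graph:

- *random* — unbiased random walk, 1400 trials;
- *eulerian* — concatenated random Eulerian circuits (each covers all 30
  edges exactly once; randomized Hierholzer construction), truncated at
  1395 trials;
- *hamiltonian* — concatenated Hamiltonian paths (each presents all 15
  nodes exactly once; sampled uniformly from the exhaustive enumeration),
  93 paths = 1395 trials, each new path starting at a neighbour of the
  previous terminal node.

**Trial features.** Community-boundary node types (*transition* = entry into
a new community, *pre-transition* = the trial before it, with the a-b-a
back-traversal rule counting only the first crossing of a re-traversed
bridge), and two repetition-priming covariates: Lag10 (occurrences of the
current image in the previous 10 trials) and Recency (trials elapsed since
it last appeared).

**Synthetic behavior.** A generative RT model conjugate to the analysis:
per-participant random intercepts and slopes, a practice effect, a
condition-specific cross-community surprisal effect, additive priming
effects, right-skewed residual noise, 15% rotated cover-task trials, and
configurable contamination (errors, timeouts, implausibly fast responses).

**Analysis.** The full pipeline: a fixed-order exclusion cascade
(incorrect → rotated → RT < 100 ms → per-subject |z| > 3 → anomalous
subjects), cover-task sensitivity A′, the per-participant surprisal
statistic, linear mixed models

```
RT ~ NodeType * Condition * Trial (+ Lag10 + Recency)
     + (1 + Trial + NodeType (+ Recency) + NodeType:Trial | participant)
```

fit by REML with a documented convergence ladder, likelihood-ratio
comparison of nested ML fits, per-condition simple effects, and
parameter-recovery simulation. Node Type is coded −0.5/+0.5 and Condition
−1/+1, so the Node Type main effect equals the mean of the per-condition
simple effects and the interaction equals half their difference.

## Worked example

```bash
python examples/03_simulate_and_analyze.py
```

simulates 20 participants per condition (random vs Hamiltonian walks) and
prints, among other things:

```
surprisal (transition minus pre-transition RT, ms):
hamiltonian     5.1
random         33.4

Model 1 (random vs hamiltonian), random effects: ('intercept', 'trial', 'node_type', 'node_type:trial')
                    term   beta    se     t   df    p
                NodeType  19.88  3.24  6.13 32.0 0.00
                   Trial -28.29  3.85 -7.34 32.0 0.00
      NodeType:Condition -13.78  3.25 -4.25 32.0 0.00

priming model NodeType beta = 14.07 ms (surprisal net of Lag10/Recency)
LRT full vs priming-only: chi2(6) = 22.71, p = 0.0008989
```

Read: RTs slow sharply at community entry in the random walk but barely in
the Hamiltonian walk (the negative NodeType × Condition interaction);
participants speed up over trials; and the walk-structure effect survives
adjustment for repetition priming, which the likelihood-ratio test confirms
is a necessary part of the model. Other example scripts build the graph and
walks (`01`), reproduce the worked Lag10/Recency example (`02`), and run a
small parameter-recovery study (`04`).

A thin CLI mirrors the library (`commwalk gen-graph | gen-walk | simulate |
analyze | recover | run-all`); `run-all` executes the whole pipeline from a
JSON config and writes a manifest that makes reruns byte-identical.

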