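# Methods

This note documents the models, numerical choices and known limitations of
`commwalk`, in the spirit of a statistical package's methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The graph

`build_community_graph(n_communities, community_size)` constructs a ring of
communities: each community is a clique minus the edge between its two
*boundary* nodes, and each boundary node carries exactly one bridge to the
adjacent community. The construction is (m−1)-regular for community size m,
so the default (3 communities of 5) gives the 15-node, 30-edge, degree-4
graph on which a random walk has uniform transition probabilities. For
3 communities of 5 this is the unique simple construction consistent with
degree-4 regularity, 30 edges and two boundary nodes per community. Which
boundary nodes pair across communities is immaterial: all ring pairings are
isomorphic, and the package uses contiguous id blocks ([0–4], [5–9],
[10–14]) with the first and last id of each block as its boundary nodes.
Image-to-node assignment is a per-participant permutation stored as run
metadata; all analysis operates on node ids, and a test asserts the labels
are invariant to it.

## Walks

*Random*: uniform start, uniform successor among the 4 neighbours.

*Hamiltonian*: paths are sampled uniformly from the exhaustive backtracking
enumeration from the required start node (lexicographic neighbour order,
cached per graph; 864 paths from each boundary node, 1296 from each internal
node). "Forward and backward" admissibility is automatic: reversing a path
that ends at *s* yields a path starting at *s*, so the enumeration from *s*
is closed under reversal. Each subsequent path starts at a uniformly drawn
neighbour of the previous terminal node; on the default graph every node
admits Hamiltonian paths (verified by enumeration), so the generator cannot
dead-end. Uniform sampling from the enumeration is a design choice — the
original procedure is described only as "randomly selected" — and is the
least biased reproducible reading.

Two structural facts that the enumeration itself establishes (and that naive
intuition gets wrong): a Hamiltonian path need **not** visit each community
in one contiguous block. 11664 of the 16848 paths are (5,5,5) with 2 bridge
traversals; the other 5184 split one community into end blocks (k,5,5,5−k),
k=1..4, using all 3 bridges, by leaving it early and re-entering at its
other, still-unvisited boundary node. Consequently a path carries 2 *or* 3
within-path community entries.

*Eulerian*: all degrees are even, so Eulerian trails are closed circuits;
"Eulerian paths" are therefore circuits by necessity (an inference, stated
here rather than assumed silently). Circuits come from a randomized
Hierholzer construction (random unused-edge choices with implicit splicing
via the stack); each new circuit starts at the previous one's terminal node
with the duplicated junction node emitted once, keeping the stream
continuous with no immediate image repeats; the final circuit is truncated
so the sequence has exactly the requested length. Randomized Hierholzer does
not sample circuits exactly uniformly (uniform sampling would need
BEST-theorem machinery, out of scope); it is used only for sequence
generation and diagnostics, where this does not matter.

*Seeding*: every stochastic step consumes a generator spawned as
`SeedSequence(root_seed, spawn_key=(condition_index, participant_index))`,
so runs are reproducible and a participant's stream does not depend on how
many participants are simulated.

### Next-step uncertainty diagnostic

For the Hamiltonian condition, the profile is exact: sample a start and a
path, and at each position compute the Shannon entropy of the next node over
the uniformly weighted enumerated paths consistent with the observed prefix.
For the Eulerian condition the ensemble is the feasibility-constrained
random-successor process: at each position the next edge is uniform over the
unused incident edges whose traversal leaves the circuit completable
(checked by connectivity of the remaining edges). This is exactly the
distribution the package's own circuit generator induces, which is what the
diagnostic is meant to describe; the conditional law of a uniform-over-
circuits ensemble would require counting Eulerian completions and is not
attempted. Both profiles are averaged over sampled prefixes. The Hamiltonian
profile is a *sawtooth*, not monotone: entropy collapses toward the end of
each community block (the remaining within-community order becomes forced)
and partially rebounds at entry into the next community; only the overall
trend decreases, reaching exactly 0 at the final position. The random-walk
profile is the constant log2(4) = 2 bits.

## Trial features

A trial is a *transition* when its community differs from the previous
trial's, except that when a bridge edge is immediately re-traversed
backwards (a-b-a) only the first crossing counts; the suppression window is
deliberately limited to the immediate lag-2 return. *Pre-transition* is the
trial immediately before a counted transition; on the ring construction a
counted transition can never directly follow another (each boundary node has
a single bridge), so the two labels are disjoint by construction, and the
precedence rule (transition wins) is defensive. Lag10 uses the literal
previous-10-trials window, clipped at the sequence start. Recency is trials
elapsed since the last occurrence (x-y-x scores 2) and is undefined (NaN) at
first occurrences — an immediate repeat is impossible on a simple graph, so
0 cannot occur under this convention; an alternative "exclusive" convention
(intervening trials, so x-y-x scores 1 and an immediate repeat would score
0) is available behind a flag for comparability with datasets indexed that
way. Rows with undefined recency are dropped only from models that include
Recency.

## Generative RT model

For participant *i* on trial *t*:

RT = b0_i + b1_i·trial_z + b2_i·node + βL·lag10_c + βR·recency_c + ε

with b0_i ~ N(800, 100²) ms, b1_i ~ N(−31, 25²) ms per SD of trial number,
b2_i ~ N(s_cond, 12²) ms on the node contrast (pre-transition −0.5,
transition +0.5, other 0; so b2 is the transition-minus-pre difference), and
ε a mean-zero shifted lognormal (shape 0.5) with SD 150 ms — gaussian
noise is available for exact conjugacy checks. Default surprisal means
s_cond are 19 ms (random, eulerian) and 2 ms (hamiltonian), and the priming
defaults are −6 ms per Lag10 occurrence and +8 ms per Recency unit. These
magnitudes are calibration anchors chosen to produce effect patterns of the
kind this paradigm reports, not ground truth.

Predictor scales are shared exactly with the analysis: trial is
standardized; lag10 is centered on its raw occurrence scale; recency is
centered and divided by a **fixed** constant `RECENCY_SCALE = 20` trials
(about one SD of recency in these walks). The fixed constant — rather than a
data-dependent SD — keeps the generator conjugate to the fitted model, and a
raw-trial scale is ruled out on internal-consistency grounds: a
several-ms-per-trial recency slope would dwarf every other effect, which is
incompatible with how little a priming adjustment of this kind moves the
node-type effect.

Cover task: each trial is rotated with probability 0.15; responses are wrong
with probability 0.089 and time out with a configurable probability
(default 0), both independent of node type so cover-task noise cannot
masquerade as surprisal. A configurable fraction (default 0.027) of RTs is
replaced by implausibly fast values (< 100 ms) to exercise the exclusion
floor. The response deadline and any dependence of errors on rotation status
are unknown in this paradigm; both are exposed as configuration. Effects are
stationary within a run — no learning dynamics are modeled.

## Analysis pipeline

*Exclusions* run in a fixed, tested order: (1) incorrect responses
(timeouts count as incorrect); (2) rotated trials; (3) RTs strictly below
100 ms (exactly 100 ms survives); (4) per subject, z-scored RTs with
|z| > 3 removed ("standardized" outlier trimming is read as the common
reading-time convention: z-score each subject's RTs, cut at 3 SD); (5) any
subject losing more than a threshold fraction (default 0.5) of their trials
cumulatively is dropped entirely — published uses of this paradigm drop
subjects with extreme (>90%) cumulative loss without stating a rule, so the
threshold is configurable. Every stage reports counts and pre-stage
fractions.

*A′* uses the Pollack–Norman closed form, 0.5 at H = F; per-participant
rates use a half-count continuity correction only for empty cells (no
trials of a class). The single-point trapezoidal AUC (1+H−F)/2 is a strict
lower bound of A′ (tight at chance and at perfection), which the tests use
as a geometric cross-check alongside hand-computed values.

*Mixed models* are statsmodels MixedLM fits. REML is used for reported
coefficients, ML for likelihood-ratio comparisons. The fullest random-effects
structure is requested first and simplified on non-convergence in the
documented order NodeType:Trial → Recency → NodeType → Trial (intercept
always kept); every fit records the rung used, and near-zero random-effect
variances flag the fit as singular rather than passing silently. The powell
optimizer is tried first (empirically the most reliable on these variance
profiles), then statsmodels' default gradient sequence. p-values use a
between-within containment t approximation: group-level degrees of freedom
(participants minus the number of group-level terms) for the intercept,
participant-constant terms, and terms carrying or interacting with a fitted
random slope; residual degrees of freedom otherwise. This is the standard
conservative fallback where no Satterthwaite approximation is available,
and the df rule is recorded on every fit. Residual-df inference for
group-limited terms was measurably anticonservative in recovery simulations,
which is why the containment rule is the default.

*Model comparison*: the likelihood-ratio statistic 2(llf_full − llf_reduced)
with df equal to the fixed-effect count difference, on ML fits over
identical rows; REML fits and non-nested specs are rejected. For the
standard comparison (full priming model vs Trial+Lag10+Recency only) the df
is 6.

*Simple effects* re-fit NodeType + Trial within each condition, sharing the
combined model's predictor encoding so the contrast algebra holds: the
combined NodeType main effect equals the mean of the per-condition simple
effects and the interaction half their difference — exact for fully
interacted least squares, and holding to a fraction of a millisecond for
mixed fits (the residual discrepancy comes from pooled vs per-condition
variance-component estimates and is second-order in the sample size).

*Parameter recovery* repeats simulate → exclude → fit with the priming model
whose random-effects structure matches the generator (intercept, Trial and
NodeType slopes), and reports per-term bias, RMSE, CI coverage at the
fit's own df, rejection rates, and the convergence rate. The exclusion
cascade itself induces a small attenuation of every slope (trimming on RT
removes disproportionately the trials with the largest predicted RTs,
especially under right-skewed noise) — of order 5% of the effect size at the
default settings — which is a property of the prescribed pipeline, not of
the estimator, and is visible in the recovery report's bias column.

## What the synthetic data do and do not establish

The generator reproduces the *structure* the analysis assumes: random
participant heterogeneity, walk-dependent surprisal, priming tied to the
actual lag/recency statistics of each walk, realistic contamination and
right-skewed noise. It does not emulate learning dynamics (effects are
constant from trial 1), response deadlines, rotation-dependent error rates,
sequence-position autocorrelation in noise, or any image-specific
idiosyncrasy. Passing recovery and calibration tests therefore shows the
pipeline is correct and well-calibrated *under its assumed data-generating
process* — it cannot certify conclusions about human data, whose generating
process is unknown and which were never deposited for this paradigm.

## Problem sizes

Defaults mirror the emulated design: 20 participants per condition, walks of
1400/1395/1395 trials. Recovery and type-I calibration use 200 replicates of
the two-condition design (40 participants, ≈56k simulated trials per
replicate), a size at which Monte-Carlo error on a coverage estimate is
about ±0.015. Unit tests use smaller rosters (3–8 participants) chosen to
exercise every code path quickly.
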