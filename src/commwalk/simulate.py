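"""Synthetic multi-participant reaction-time streams.

This module is the generative inverse of the analysis models: per-participant
random intercepts and slopes, a practice (trial) effect, condition-specific
cross-community surprisal effects carried by the node-type contrast, additive
Lag10/Recency repetition-priming effects, a rotation cover task, and
configurable contamination (incorrect responses, timeouts, implausibly fast
RTs).  Defaults are calibration anchors chosen to echo plausible magnitudes
for this kind of experiment: ~19 ms surprisal in the redundant (random /
Eulerian) walks versus ~2 ms in the Hamiltonian walk, a -31 ms practice
effect per SD of trial number, -6 ms per Lag10 occurrence and +8 ms per
recency unit (one unit = 20 trials elapsed), 15% rotated trials and 8.9%
incorrect responses.

Predictor scales match the analysis exactly: trial is standardized, node
type enters as a centered two-level contrast (pre-transition -0.5,
transition +0.5, other nodes 0), Lag10 is centered on its raw scale, and
Recency is centered and divided by the fixed ``RECENCY_SCALE`` constant.
Residual noise is a mean-zero shifted lognormal by default (RT-like right
skew); a gaussian family is available for exact conjugacy checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .graph import CommunityGraph, build_community_graph
from .features import assemble_trial_features
from .walks import (WalkSequence, random_walk, eulerian_sequence,
                    hamiltonian_sequence)

__all__ = [
    "GenerativeParams",
    "NODE_CODE",
    "draw_participant_effects",
    "simulate_rts",
    "simulate_cover_task",
    "simulate_experiment",
    "DEFAULT_WALK_LENGTHS",
]

#: Node-type contrast used by both the generator and the analysis.
NODE_CODE = {"pre_transition": -0.5, "transition": 0.5, "other": 0.0}

#: Fixed scale (trials) for the Recency predictor.  Recency is centered and
#: divided by this constant in both the generator and the analysis, so its
#: coefficient reads "ms per ~20 trials elapsed" (about one SD of recency)
#: and the two sides share one scale exactly.  A fixed constant, unlike a
#: data-dependent SD, keeps the generative model conjugate to the fit.
RECENCY_SCALE = 20.0

#: Exposure lengths per condition (trials).
DEFAULT_WALK_LENGTHS = {"random": 1400, "eulerian": 1395, "hamiltonian": 1395}


@dataclass
class GenerativeParams:
    """All coefficients and noise scales of the synthetic RT model.

    Units are milliseconds unless noted.  ``surprisal_effect`` maps each
    condition to the transition-minus-pre-transition RT difference its
    participants carry on average; ``trial_slope_mean`` is per standardized
    trial unit; ``lag10_effect`` is per occurrence in the 10-trial window;
    ``recency_effect`` is per ``RECENCY_SCALE`` (20) trials elapsed.
    """

    grand_intercept: float = 800.0
    intercept_sd: float = 100.0
    trial_slope_mean: float = -31.0
    trial_slope_sd: float = 25.0
    surprisal_effect: dict = field(default_factory=lambda: {
        "random": 19.0, "eulerian": 19.0, "hamiltonian": 2.0})
    surprisal_effect_sd: float = 12.0
    lag10_effect: float = -6.0
    recency_effect: float = 8.0
    residual_sd: float = 150.0
    residual_family: str = "lognormal"   # or "gaussian"
    log_shape: float = 0.5               # skew of the lognormal family
    rotation_rate: float = 0.15
    error_rate: float = 0.089
    timeout_rate: float = 0.0
    implausible_rt_rate: float = 0.027
    n_participants: int = 20
    seed: int = 0

    def __post_init__(self):
        for name in ("rotation_rate", "error_rate", "timeout_rate",
                     "implausible_rt_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("intercept_sd", "trial_slope_sd", "surprisal_effect_sd",
                     "residual_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if self.residual_family not in ("gaussian", "lognormal"):
            raise ValueError(f"unknown residual_family {self.residual_family!r}")

    def null(self) -> "GenerativeParams":
        """Copy with all fixed-effect means zeroed (variances kept).

        Used for type-I-error calibration: participant heterogeneity and
        noise stay realistic while every systematic effect is removed.
        """
        return replace(self,
                       trial_slope_mean=0.0,
                       surprisal_effect={k: 0.0 for k in self.surprisal_effect},
                       lag10_effect=0.0, recency_effect=0.0)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GenerativeParams":
        return cls(**d)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def draw_participant_effects(params: GenerativeParams, n: int,
                             seed=None, condition: str = "random"
                             ) -> pd.DataFrame:
    """Draw per-participant intercepts and slopes from the population model."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    return pd.DataFrame({
        "participant": np.arange(n),
        "intercept": rng.normal(params.grand_intercept, params.intercept_sd, n),
        "trial_slope": rng.normal(params.trial_slope_mean,
                                  params.trial_slope_sd, n),
        "node_effect": rng.normal(params.surprisal_effect[condition],
                                  params.surprisal_effect_sd, n),
    })


def _residual_noise(params: GenerativeParams, n: int,
                    rng: np.random.Generator) -> np.ndarray:
    if params.residual_sd == 0:
        return np.zeros(n)
    if params.residual_family == "gaussian":
        return rng.normal(0.0, params.residual_sd, n)
    # shifted lognormal standardized to mean 0, sd residual_sd
    s = params.log_shape
    x = np.exp(rng.normal(0.0, s, n))
    mean = np.exp(s * s / 2.0)
    sd = np.sqrt((np.exp(s * s) - 1.0) * np.exp(s * s))
    return params.residual_sd * (x - mean) / sd


def simulate_rts(features: pd.DataFrame, effects, params: GenerativeParams,
                 seed=None) -> pd.DataFrame:
    """Add an ``rt`` column to a single participant's trial-feature table.

    rt = intercept_i + slope_i * trial_std + node_effect_i * nodecode
         + lag10_effect * lag10_c + recency_effect * recency_c + noise

    where trial_std is the standardized trial number, nodecode the centered
    node-type contrast, and _c marks covariates centered over this walk
    (missing recency contributes 0).  RTs are floored at 1 ms.
    """
    rng = _as_rng(seed)
    out = features.copy()
    trial = out["trial"].to_numpy(dtype=float)
    sd = trial.std()
    trial_std = (trial - trial.mean()) / sd if sd > 0 else trial * 0.0
    nodecode = out["node_type"].map(NODE_CODE).to_numpy(dtype=float)
    lag10 = out["lag10"].to_numpy(dtype=float)
    lag10_c = lag10 - lag10.mean()
    rec = out["recency"].to_numpy(dtype=float)
    rec_c = np.where(np.isnan(rec), 0.0,
                     (rec - np.nanmean(rec)) / RECENCY_SCALE)
    mu = (float(effects["intercept"])
          + float(effects["trial_slope"]) * trial_std
          + float(effects["node_effect"]) * nodecode
          + params.lag10_effect * lag10_c
          + params.recency_effect * rec_c)
    out["rt"] = np.maximum(mu + _residual_noise(params, len(out), rng), 1.0)
    return out


def simulate_cover_task(walk, params: GenerativeParams,
                        seed=None) -> pd.DataFrame:
    """Rotation flags, responses and correctness for the orientation task.

    Each trial is independently rotated with probability ``rotation_rate``;
    responses are wrong with probability ``error_rate`` (independent of
    rotation status, so cover-task noise cannot masquerade as a node-type
    effect) and time out with probability ``timeout_rate`` (counted
    incorrect).
    """
    n = len(walk) if not isinstance(walk, int) else walk
    if n < 1:
        raise ValueError("walk is empty")
    rng = _as_rng(seed)
    rotated = rng.random(n) < params.rotation_rate
    timeout = rng.random(n) < params.timeout_rate
    wrong = rng.random(n) < params.error_rate
    respond_rotated = rotated ^ wrong
    response = np.where(timeout, "timeout",
                        np.where(respond_rotated, "rotated", "canonical"))
    correct = ~timeout & ~wrong
    return pd.DataFrame({"rotated": rotated, "response": response,
                         "correct": correct})


def _make_walk(graph: CommunityGraph, condition: str, length: int,
               rng: np.random.Generator) -> WalkSequence:
    if condition == "random":
        return random_walk(graph, length, rng)
    if condition == "eulerian":
        return eulerian_sequence(graph, length, rng)
    if condition == "hamiltonian":
        n_paths, rem = divmod(length, graph.n_nodes)
        if rem:
            raise ValueError(
                f"hamiltonian length {length} is not a multiple of "
                f"{graph.n_nodes}")
        return hamiltonian_sequence(graph, n_paths, rng)
    raise ValueError(f"unknown condition {condition!r}")


def simulate_experiment(params: GenerativeParams, seed: int | None = None,
                        graph: CommunityGraph | None = None,
                        conditions=("random", "eulerian", "hamiltonian"),
                        walk_lengths: dict | None = None) -> pd.DataFrame:
    """Full multi-condition trial table: walks, covariates, cover task, RTs.

    One fresh walk per participant; every stochastic step consumes an rng
    spawned from ``SeedSequence(seed, spawn_key=(condition_index,
    participant_index))``, so tables are reproducible and participants'
    streams are independent of how many are simulated.  Per-participant
    image permutations (image-to-node assignment) are stored in
    ``table.attrs['image_permutation']`` but never used by the analysis,
    which operates on node ids.
    """
    if graph is None:
        graph = build_community_graph()
    lengths = dict(DEFAULT_WALK_LENGTHS)
    if walk_lengths:
        lengths.update(walk_lengths)
    chunks = []
    permutations = {}
    for ci, condition in enumerate(conditions):
        for p in range(params.n_participants):
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(ci, p)))
            pid = f"{condition}_{p:02d}"
            permutations[pid] = rng.permutation(graph.n_nodes).tolist()
            walk = _make_walk(graph, condition, lengths[condition], rng)
            feats = assemble_trial_features(walk, graph)
            effects = {
                "intercept": rng.normal(params.grand_intercept,
                                        params.intercept_sd),
                "trial_slope": rng.normal(params.trial_slope_mean,
                                          params.trial_slope_sd),
                "node_effect": rng.normal(params.surprisal_effect[condition],
                                          params.surprisal_effect_sd),
            }
            trials = simulate_rts(feats, effects, params, rng)
            cover = simulate_cover_task(walk, params, rng)
            trials = pd.concat([trials, cover], axis=1)
            fast = rng.random(len(trials)) < params.implausible_rt_rate
            if fast.any():
                trials.loc[fast, "rt"] = rng.uniform(1.0, 100.0, fast.sum())
            trials.insert(0, "participant", pid)
            trials.insert(1, "condition", condition)
            chunks.append(trials)
    table = pd.concat(chunks, ignore_index=True)
    table.attrs["image_permutation"] = permutations
    table.attrs["seed"] = seed
    return table
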