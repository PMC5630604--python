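"""End-to-end reproducible runs: one JSON config in, run artifacts out.

A :class:`RunConfig` is the single source of truth for a run: graph
parameters, per-condition walk lengths, the generative RT model, exclusion
settings, the models to fit, and a root seed.  ``run_pipeline`` executes
graph -> walks -> features -> simulation -> exclusions -> models -> reports
and writes a manifest (resolved config + sha256 of every artifact) so a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import (MODEL_SPECS, apply_exclusions, cover_task_summary,
                       encode_predictors, fit_mixed_model,
                       likelihood_ratio_test, surprisal_summary)
from .features import assemble_trial_features
from .graph import build_community_graph, graph_to_json, validate_graph
from .simulate import (DEFAULT_WALK_LENGTHS, GenerativeParams,
                       simulate_experiment, _make_walk)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything that determines a run; serializes losslessly to JSON."""

    n_communities: int = 3
    community_size: int = 5
    conditions: tuple = ("random", "eulerian", "hamiltonian")
    walk_lengths: dict = field(
        default_factory=lambda: dict(DEFAULT_WALK_LENGTHS))
    gen: GenerativeParams = field(default_factory=GenerativeParams)
    rt_floor: float = 100.0
    sd_cutoff: float = 3.0
    subject_loss_threshold: float = 0.5
    models: tuple = ("model1", "model2", "model3", "priming")
    seed: int = 0

    def to_json(self) -> str:
        d = asdict(self)
        d["conditions"] = list(self.conditions)
        d["models"] = list(self.models)
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        if "gen" in d:
            d["gen"] = GenerativeParams.from_dict(d["gen"])
        if "conditions" in d:
            d["conditions"] = tuple(d["conditions"])
        if "models" in d:
            d["models"] = tuple(d["models"])
        return cls(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _walk_frame(walk, graph) -> pd.DataFrame:
    feats = assemble_trial_features(walk, graph)
    return feats[["trial", "node_id", "community", "path_index",
                  "within_path_position"]]


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full pipeline and write all artifacts under ``out_dir``.

    Models whose conditions are absent from the config are skipped with an
    explicit notice in the manifest.  Returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    notices: list[str] = []

    graph = build_community_graph(config.n_communities, config.community_size)
    report = validate_graph(graph)
    if not report.ok:
        raise RuntimeError(f"graph validation failed: {report.failed()}")
    p = out / "graph.json"
    p.write_text(graph_to_json(graph))
    written["graph"] = p

    # one example walk per condition (seeded independently of participants)
    for ci, condition in enumerate(config.conditions):
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(1000 + ci,)))
        walk = _make_walk(graph, condition, config.walk_lengths[condition],
                          rng)
        p = out / f"walk_{condition}.csv"
        _walk_frame(walk, graph).to_csv(p, index=False)
        written[f"walk_{condition}"] = p

    table = simulate_experiment(config.gen, seed=config.seed, graph=graph,
                                conditions=config.conditions,
                                walk_lengths=config.walk_lengths)
    p = out / "trials.csv"
    table.to_csv(p, index=False)
    written["trials"] = p

    kept, excl = apply_exclusions(
        table, rt_floor=config.rt_floor, sd_cutoff=config.sd_cutoff,
        subject_loss_threshold=config.subject_loss_threshold)
    p = out / "exclusions.json"
    p.write_text(json.dumps(excl.to_dict(), indent=1))
    written["exclusions"] = p

    cover = cover_task_summary(table)
    p = out / "cover_task.json"
    p.write_text(json.dumps(cover.to_dict(), indent=1))
    written["cover_task"] = p

    p = out / "surprisal.csv"
    surprisal_summary(kept).to_csv(p, index=False)
    written["surprisal"] = p

    fits = {}
    for name in config.models:
        spec = MODEL_SPECS[name]
        missing = set(spec.conditions) - set(config.conditions)
        if missing:
            notices.append(
                f"model {name!r} skipped: conditions {sorted(missing)} "
                "not simulated")
            continue
        df, coding = encode_predictors(kept, spec)
        fit = fit_mixed_model(df, spec, coding=coding)
        fits[name] = fit
        p = out / f"model_{name}_coefficients.csv"
        fit.summary_frame().to_csv(p, index=False)
        written[f"model_{name}"] = p

    if "priming" in fits:
        spec_full = MODEL_SPECS["priming"]
        spec_red = MODEL_SPECS["priming_reduced"]
        df, coding = encode_predictors(kept, spec_full)
        full_ml = fit_mixed_model(df, spec_full, reml=False, coding=coding)
        red_ml = fit_mixed_model(df, spec_red, reml=False, coding=coding)
        lrt = likelihood_ratio_test(full_ml, red_ml)
        p = out / "priming_lrt.json"
        p.write_text(json.dumps(lrt.to_dict(), indent=1))
        written["priming_lrt"] = p

    manifest = {
        "config": json.loads(config.to_json()),
        "graph_validation": report.to_dict(),
        "artifacts": {k: str(v.name) for k, v in written.items()},
        "sha256": {k: _sha256(v) for k, v in written.items()},
        "notices": notices,
    }
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
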