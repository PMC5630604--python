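"""Reaction-time analysis: exclusions, sensitivity, surprisal, mixed models.

The analysis mirrors a standard trial-level RT workflow:

1. a fixed-order exclusion cascade (incorrect -> rotated -> implausibly fast
   -> per-subject 3 SD outliers -> anomalous subjects);
2. cover-task sensitivity via the nonparametric A' index;
3. the per-participant surprisal statistic, mean RT(transition) minus mean
   RT(pre-transition);
4. linear mixed-effects models regressing RT on Node Type, Condition and
   Trial (all interactions), optionally with Lag10/Recency priming
   covariates, fit with statsmodels MixedLM under a convergence ladder of
   progressively simplified random-effects structures;
5. nested model comparison by likelihood-ratio test on ML fits, per-condition
   simple-effects fits, and end-to-end parameter-recovery simulation.

Contrast coding pins the usual simple-effects algebra: Node Type is a
centered two-level contrast (pre-transition -0.5 / transition +0.5) so its
coefficient is the transition-minus-pre difference, and Condition is coded
-1/+1 so the Node Type main effect equals the mean of the per-condition
simple effects and the Node Type x Condition interaction equals half their
difference.  Trial is standardized within the modeled data; Lag10 is
centered on its raw scale; Recency is centered and expressed per
RECENCY_SCALE (20) trials, a fixed constant shared with the generator.

Fixed-effect p-values use a between-within containment t approximation
(statsmodels provides no Satterthwaite approximation): terms whose
information is limited by the number of participants — the intercept,
participant-constant terms such as Condition, and any term carrying or
interacting with a fitted random slope — get group-level degrees of freedom
(n_participants minus the number of such terms), everything else residual
degrees of freedom (nobs minus the number of fixed effects).  The rule is
recorded as ``df_method`` and the per-term df on every fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from statsmodels.regression.mixed_linear_model import MixedLM

from .simulate import (GenerativeParams, NODE_CODE, RECENCY_SCALE,
                       simulate_experiment)

__all__ = [
    "ExclusionReport",
    "apply_exclusions",
    "a_prime",
    "CoverTaskSummary",
    "cover_task_summary",
    "surprisal_summary",
    "ModelSpec",
    "MODEL_SPECS",
    "encode_predictors",
    "ModelFitResult",
    "fit_mixed_model",
    "fit_priming_model",
    "LRTResult",
    "likelihood_ratio_test",
    "simple_effects",
    "RecoveryReport",
    "parameter_recovery",
]


# ---------------------------------------------------------------------------
# exclusions
# ---------------------------------------------------------------------------

@dataclass
class ExclusionReport:
    """Per-stage removal counts for the fixed-order exclusion cascade.

    Each stage dict records the row count before the stage, the rows
    removed, and the removed fraction relative to the pre-stage count.
    """

    stages: list = field(default_factory=list)
    subject_retained_fraction: dict = field(default_factory=dict)
    dropped_subjects: list = field(default_factory=list)
    n_input: int = 0
    n_output: int = 0

    def add_stage(self, name: str, before: int, removed: int) -> None:
        self.stages.append({
            "stage": name, "before": before, "removed": removed,
            "fraction": removed / before if before else 0.0,
        })

    def removed(self, stage: str) -> int:
        for s in self.stages:
            if s["stage"] == stage:
                return s["removed"]
        raise KeyError(stage)

    def to_dict(self) -> dict:
        return {
            "stages": list(self.stages),
            "subject_retained_fraction": dict(self.subject_retained_fraction),
            "dropped_subjects": list(self.dropped_subjects),
            "n_input": self.n_input,
            "n_output": self.n_output,
        }


class UnusableDataError(RuntimeError):
    """Raised when an exclusion stage leaves nothing to analyze."""


def apply_exclusions(table: pd.DataFrame, rt_floor: float = 100.0,
                     sd_cutoff: float = 3.0,
                     subject_loss_threshold: float = 0.5
                     ) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the five-stage exclusion cascade, in fixed order.

    1. drop incorrect responses (timeouts count as incorrect);
    2. drop rotated-image trials;
    3. drop implausibly fast trials, rt strictly below ``rt_floor``
       (a trial at exactly the floor survives);
    4. per subject, z-score the remaining RTs and drop |z| > ``sd_cutoff``;
    5. drop any subject whose cumulative removed fraction exceeds
       ``subject_loss_threshold``.
    """
    required = {"participant", "correct", "rotated", "rt"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table lacks required columns: {sorted(missing)}")

    report = ExclusionReport(n_input=len(table))
    original_per_subject = table.groupby("participant").size()

    df = table
    for name, keep in [
        ("incorrect", lambda d: d["correct"].astype(bool)),
        ("rotated", lambda d: ~d["rotated"].astype(bool)),
        ("implausible_rt", lambda d: d["rt"] >= rt_floor),
    ]:
        before = len(df)
        mask = keep(df)
        report.add_stage(name, before, int((~mask).sum()))
        df = df[mask]
        if df.empty:
            report.n_output = 0
            raise UnusableDataError(f"no rows left after stage '{name}'")

    before = len(df)
    z = df.groupby("participant")["rt"].transform(
        lambda s: (s - s.mean()) / s.std(ddof=1) if s.std(ddof=1) > 0
        else s * 0.0)
    mask = z.abs() <= sd_cutoff
    report.add_stage("outlier_3sd", before, int((~mask).sum()))
    df = df[mask]
    if df.empty:
        report.n_output = 0
        raise UnusableDataError("no rows left after stage 'outlier_3sd'")

    retained = df.groupby("participant").size()
    frac = (retained.reindex(original_per_subject.index, fill_value=0)
            / original_per_subject)
    report.subject_retained_fraction = frac.to_dict()
    dropped = frac.index[(1.0 - frac) > subject_loss_threshold].tolist()
    before = len(df)
    df = df[~df["participant"].isin(dropped)]
    report.add_stage("subject_level", before, before - len(df))
    report.dropped_subjects = dropped
    if df.empty:
        report.n_output = 0
        raise UnusableDataError("no rows left after stage 'subject_level'")

    report.n_output = len(df)
    return df.reset_index(drop=True), report


# ---------------------------------------------------------------------------
# cover-task sensitivity
# ---------------------------------------------------------------------------

def a_prime(hit_rate: float, false_alarm_rate: float) -> float:
    """Nonparametric sensitivity A' (Pollack-Norman closed form).

    A' = 0.5 + sign(H - F) * [(H - F)^2 + |H - F|] / [4 max(H, F) - 4 H F],
    equal to 0.5 at chance (H = F) and 1.0 for perfect sensitivity.
    """
    h, f = float(hit_rate), float(false_alarm_rate)
    if not (0.0 <= h <= 1.0 and 0.0 <= f <= 1.0):
        raise ValueError("rates must be in [0, 1]")
    if h == f:
        return 0.5
    sign = 1.0 if h > f else -1.0
    num = (h - f) ** 2 + abs(h - f)
    den = 4.0 * max(h, f) - 4.0 * h * f
    return 0.5 + sign * num / den


def _rate(k: int, n: int) -> float:
    # empty cells get the half-count continuity correction (-> 0.5)
    if n == 0:
        return (k + 0.5) / (n + 1)
    return k / n


@dataclass
class CoverTaskSummary:
    per_participant: pd.DataFrame
    mean_a_prime: float
    sd_a_prime: float
    t_statistic: float
    p_value: float
    df: int

    def to_dict(self) -> dict:
        return {"mean_a_prime": self.mean_a_prime,
                "sd_a_prime": self.sd_a_prime,
                "t_statistic": self.t_statistic,
                "p_value": self.p_value, "df": self.df}


def cover_task_summary(table: pd.DataFrame) -> CoverTaskSummary:
    """Per-participant hit/false-alarm rates and A', plus a one-sample
    t-test of the group A' against chance (0.5)."""
    rows = []
    for pid, d in table.groupby("participant"):
        said_rotated = d["response"] == "rotated"
        rot, canon = d["rotated"].astype(bool), ~d["rotated"].astype(bool)
        h = _rate(int((said_rotated & rot).sum()), int(rot.sum()))
        f = _rate(int((said_rotated & canon).sum()), int(canon.sum()))
        rows.append({"participant": pid, "hit_rate": h,
                     "false_alarm_rate": f, "a_prime": a_prime(h, f)})
    per = pd.DataFrame(rows)
    a = per["a_prime"].to_numpy()
    if len(a) >= 2 and a.std(ddof=1) > 0:
        t, p = stats.ttest_1samp(a, 0.5)
    else:
        t, p = float("nan"), float("nan")  # single participant: no group test
    sd = float(a.std(ddof=1)) if len(a) >= 2 else float("nan")
    return CoverTaskSummary(per, float(a.mean()), sd,
                            float(t), float(p), len(a) - 1)


# ---------------------------------------------------------------------------
# surprisal statistic
# ---------------------------------------------------------------------------

def surprisal_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-participant mean RTs for pre-transition and transition trials.

    ``difference`` = transition mean - pre-transition mean; a positive value
    is an RT increase upon entry into a new community.  Participants lacking
    either node type are skipped with a warning.
    """
    boundary = table[table["node_type"].isin(["pre_transition", "transition"])]
    if boundary.empty:
        raise UnusableDataError("table contains no boundary-node trials")
    rows = []
    for (pid,), d in boundary.groupby(["participant"]):
        means = d.groupby("node_type")["rt"].mean()
        if not {"pre_transition", "transition"} <= set(means.index):
            warnings.warn(f"participant {pid} lacks a node type; skipped")
            continue
        cond = d["condition"].iloc[0] if "condition" in d else None
        rows.append({
            "participant": pid, "condition": cond,
            "pre_transition_mean": means["pre_transition"],
            "transition_mean": means["transition"],
            "difference": means["transition"] - means["pre_transition"],
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model specification and predictor encoding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Fixed effects, contrast coding and random-effects structure of a model.

    ``conditions`` lists one or two condition labels; with two, Condition is
    coded -1 (first) / +1 (second) and all Node Type x Condition x Trial
    interactions enter the fixed part.  ``include_structure=False`` drops
    Node Type and Condition entirely (the reduced model of the priming
    comparison).  ``re_terms`` is the *fullest* random-effects structure;
    fitting walks down a documented ladder from it on non-convergence.
    """

    name: str
    conditions: tuple
    include_priming: bool = False
    include_structure: bool = True
    node_types: str = "boundary"       # or "all"
    re_terms: tuple = ("intercept", "trial", "node_type", "node_type:trial")
    reml: bool = True

    def __post_init__(self):
        if len(self.conditions) not in (1, 2):
            raise ValueError("conditions must have 1 or 2 entries")
        if self.node_types not in ("boundary", "all"):
            raise ValueError(f"unknown node_types {self.node_types!r}")


MODEL_SPECS = {
    "model1": ModelSpec("model1", ("random", "hamiltonian")),
    "model2": ModelSpec("model2", ("random", "eulerian")),
    "model3": ModelSpec("model3", ("eulerian", "hamiltonian")),
    # priming model: adds Lag10 + Recency, random slopes for Trial, Node
    # Type, Recency and the Trial x Node Type interaction
    "priming": ModelSpec("priming", ("random", "hamiltonian"),
                         include_priming=True,
                         re_terms=("intercept", "trial", "node_type",
                                   "recency", "node_type:trial")),
    "priming_reduced": ModelSpec("priming_reduced", ("random", "hamiltonian"),
                                 include_priming=True, include_structure=False,
                                 re_terms=("intercept", "trial", "node_type",
                                           "recency", "node_type:trial")),
}


def encode_predictors(table: pd.DataFrame, spec: ModelSpec
                      ) -> tuple[pd.DataFrame, dict]:
    """Filter to the spec's rows and attach model-ready predictor columns.

    Adds ``nodecode`` (centered two-level contrast), ``condcode`` (-1/+1),
    ``trial_std`` (z-scored within the modeled data), ``lag10_c`` and
    ``recency_c`` (centered raw scales).  Returns the encoded table and a
    coding-metadata dict.
    """
    known = set(table["condition"].unique())
    unknown = set(spec.conditions) - known
    if unknown:
        raise ValueError(f"conditions absent from table: {sorted(unknown)}")
    df = table[table["condition"].isin(spec.conditions)].copy()
    if spec.node_types == "boundary":
        df = df[df["node_type"].isin(["pre_transition", "transition"])]
    if spec.include_priming:
        df = df[df["recency"].notna()]
    if df.empty:
        raise UnusableDataError("no rows left to model after filtering")

    cond_codes = ({spec.conditions[0]: -1.0, spec.conditions[1]: 1.0}
                  if len(spec.conditions) == 2 else {spec.conditions[0]: 0.0})
    bad_types = set(df["node_type"].unique()) - set(NODE_CODE)
    if bad_types:
        raise ValueError(f"unknown node_type levels: {sorted(bad_types)}")
    df["nodecode"] = df["node_type"].map(NODE_CODE).astype(float)
    df["condcode"] = df["condition"].map(cond_codes).astype(float)
    trial = df["trial"].to_numpy(dtype=float)
    t_mean, t_sd = trial.mean(), trial.std()
    df["trial_std"] = (trial - t_mean) / t_sd if t_sd > 0 else 0.0
    coding = {"node_type": dict(NODE_CODE), "condition": cond_codes,
              "trial_mean": t_mean, "trial_sd": t_sd}
    if "lag10" in df:
        m = df["lag10"].mean()
        df["lag10_c"] = df["lag10"] - m
        coding["lag10_mean"] = float(m)
    if "recency" in df:
        m = df["recency"].mean()
        df["recency_c"] = ((df["recency"] - m) / RECENCY_SCALE).fillna(0.0)
        coding["recency_mean"] = float(m)
        coding["recency_scale"] = RECENCY_SCALE
    return df, coding


def _fixed_design(df: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    X = pd.DataFrame({"Intercept": np.ones(len(df))}, index=df.index)
    two = len(spec.conditions) == 2
    if spec.include_structure:
        X["NodeType"] = df["nodecode"]
        if two:
            X["Condition"] = df["condcode"]
    X["Trial"] = df["trial_std"]
    if spec.include_structure and two:
        X["NodeType:Condition"] = df["nodecode"] * df["condcode"]
        X["NodeType:Trial"] = df["nodecode"] * df["trial_std"]
        X["Condition:Trial"] = df["condcode"] * df["trial_std"]
        X["NodeType:Condition:Trial"] = (df["nodecode"] * df["condcode"]
                                         * df["trial_std"])
    elif spec.include_structure and not two:
        X["NodeType:Trial"] = df["nodecode"] * df["trial_std"]
    if spec.include_priming:
        X["Lag10"] = df["lag10_c"]
        X["Recency"] = df["recency_c"]
    return X


_RE_COLUMNS = {
    "intercept": lambda d: np.ones(len(d)),
    "trial": lambda d: d["trial_std"].to_numpy(),
    "node_type": lambda d: d["nodecode"].to_numpy(),
    "recency": lambda d: d["recency_c"].to_numpy(),
    "node_type:trial": lambda d: (d["nodecode"] * d["trial_std"]).to_numpy(),
}

# order in which random-effects terms are dropped on non-convergence
_LADDER_DROP_ORDER = ("node_type:trial", "recency", "node_type", "trial")


def _re_ladder(re_terms: tuple) -> list[tuple]:
    rungs = [tuple(re_terms)]
    current = list(re_terms)
    for term in _LADDER_DROP_ORDER:
        if term in current:
            current = [t for t in current if t != term]
            rungs.append(tuple(current))
    if rungs[-1] != ("intercept",):
        rungs.append(("intercept",))
    return rungs


#: fixed-effect variable -> random-effects term that carries its slope
_VAR_TO_RE = {"NodeType": "node_type", "Trial": "trial",
              "Recency": "recency", "Lag10": "lag10"}


def _term_dfs(terms: list, re_terms: tuple, n_groups: int,
              nobs: int) -> pd.Series:
    """Between-within containment df per fixed-effect term.

    A term is group-level when it is the intercept, involves a
    participant-constant variable (Condition), or any of its components has
    a fitted random slope; group-level terms share df = n_groups - (number
    of group-level terms).  Remaining terms get residual df.
    """
    slopes = {v for v, re in _VAR_TO_RE.items() if re in re_terms}
    group_level = []
    for term in terms:
        parts = term.split(":")
        group_level.append(term == "Intercept" or "Condition" in parts
                           or any(p in slopes for p in parts))
    df_group = float(max(n_groups - sum(group_level), 3))
    df_resid = float(nobs - len(terms))
    return pd.Series([df_group if g else df_resid for g in group_level],
                     index=terms)


@dataclass
class ModelFitResult:
    """Fixed-effect estimates and fit metadata for one mixed model."""

    name: str
    terms: list
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    df_terms: pd.Series
    df_resid: float
    df_method: str
    llf: float
    converged: bool
    singular: bool
    re_terms: tuple
    method: str                 # "REML" or "ML"
    nobs: int
    n_groups: int
    cov_re: pd.DataFrame | None
    scale: float
    coding: dict = field(default_factory=dict)

    def __getitem__(self, term: str) -> float:
        return float(self.params[term])

    def se(self, term: str) -> float:
        return float(self.bse[term])

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.terms,
            "beta": self.params.values,
            "se": self.bse.values,
            "t": self.tvalues.values,
            "df": self.df_terms.values,
            "p": self.pvalues.values,
        })


def _fit_once(endog, X, groups, Z, reml: bool):
    # powell is the most reliable optimizer for these variance profiles;
    # fall back to the default gradient-based sequence if it fails
    last = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(endog, X, groups=groups, exog_re=Z)
        for method in ("powell", None):
            kw = {"method": method} if method else {}
            try:
                r = model.fit(reml=reml, **kw)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if r.converged:
                return r
            last = r
    if last is None:
        raise np.linalg.LinAlgError("mixed model fit failed")
    return last


def fit_mixed_model(df: pd.DataFrame, spec: ModelSpec,
                    reml: bool | None = None,
                    re_terms: tuple | None = None,
                    coding: dict | None = None) -> ModelFitResult:
    """Fit the spec's mixed model on an encoded table.

    Walks a convergence ladder from the fullest random-effects structure,
    dropping terms in the order Node Type x Trial -> Recency -> Node Type ->
    Trial (intercept always kept), mirroring the 'fullest structure that
    converges' strategy.  The rung used is recorded in ``re_terms``;
    near-zero random-effect variances mark the fit ``singular`` (flagged,
    never silently accepted).

    Requires an encoded table (see :func:`encode_predictors`).
    """
    if df["participant"].nunique() < 2:
        raise ValueError("need at least 2 participants")
    reml = spec.reml if reml is None else reml
    X = _fixed_design(df, spec)
    endog = df["rt"].to_numpy(dtype=float)
    groups = df["participant"].to_numpy()
    ladder = _re_ladder(tuple(re_terms) if re_terms else spec.re_terms)

    result, used = None, None
    for rung in ladder:
        Z = pd.DataFrame({t: _RE_COLUMNS[t](df) for t in rung},
                         index=df.index)
        try:
            r = _fit_once(endog, X, groups, Z, reml)
        except (np.linalg.LinAlgError, ValueError):
            continue
        if r.converged and np.isfinite(r.llf) \
                and np.all(np.isfinite(r.params)):
            result, used = r, rung
            break
        if result is None:
            result, used = r, rung  # keep the first attempt as fallback
    if result is None:
        raise RuntimeError("mixed model failed on every ladder rung")

    k = X.shape[1]
    fe = result.params[:k]
    fe.index = X.columns
    bse = result.bse[:k]
    bse.index = X.columns
    tvals = fe / bse
    df_resid = float(len(df) - k)
    n_groups = int(df["participant"].nunique())
    df_terms = _term_dfs(list(X.columns), used, n_groups, len(df))
    pvals = pd.Series(2 * stats.t.sf(np.abs(tvals), df_terms),
                      index=X.columns)
    cov_re = result.cov_re
    eig = np.linalg.eigvalsh(np.asarray(cov_re))
    singular = bool(eig.min() < 1e-6 * max(result.scale, 1e-12))
    return ModelFitResult(
        name=spec.name, terms=list(X.columns), params=fe, bse=bse,
        tvalues=tvals, pvalues=pvals, df_terms=df_terms, df_resid=df_resid,
        df_method="between-within containment",
        llf=float(result.llf), converged=bool(result.converged),
        singular=singular, re_terms=used, method="REML" if reml else "ML",
        nobs=len(df), n_groups=n_groups,
        cov_re=cov_re, scale=float(result.scale), coding=coding or {})


def fit_priming_model(table: pd.DataFrame, reml: bool | None = None,
                      spec: ModelSpec | None = None) -> ModelFitResult:
    """Fit the repetition-priming model (Node Type x Condition x Trial
    + Lag10 + Recency) on a raw trial table; first-occurrence rows
    (undefined recency) are dropped."""
    spec = spec or MODEL_SPECS["priming"]
    if not spec.include_priming:
        raise ValueError("priming model spec must include priming terms")
    df, coding = encode_predictors(table, spec)
    return fit_mixed_model(df, spec, reml=reml, coding=coding)


@dataclass
class LRTResult:
    statistic: float
    df: int
    p_value: float

    def to_dict(self) -> dict:
        return {"statistic": self.statistic, "df": self.df,
                "p_value": self.p_value}


def likelihood_ratio_test(full: ModelFitResult,
                          reduced: ModelFitResult) -> LRTResult:
    """Chi-square LRT between nested ML fits on identical rows."""
    if full.method != "ML" or reduced.method != "ML":
        raise ValueError("LRT requires ML fits (refit with reml=False)")
    if full.nobs != reduced.nobs:
        raise ValueError("LRT requires identical rows in both fits")
    extra = set(reduced.terms) - set(full.terms)
    if extra or len(full.terms) <= len(reduced.terms):
        raise ValueError("models are not nested (reduced within full)")
    stat = 2.0 * (full.llf - reduced.llf)
    if stat < -1e-6:
        raise ValueError(
            f"full-model log-likelihood below reduced ({stat / 2:.4f}); "
            "optimizer failure")
    stat = max(stat, 0.0)
    df = len(full.terms) - len(reduced.terms)
    return LRTResult(float(stat), int(df), float(stats.chi2.sf(stat, df)))


def simple_effects(table: pd.DataFrame, spec: ModelSpec,
                   reml: bool | None = None,
                   re_terms: tuple = ("intercept", "trial", "node_type")
                   ) -> dict:
    """Per-condition Node Type + Trial fits after a significant interaction.

    The combined table is encoded once (so Trial shares its scaling with the
    combined model) and each condition is refit with Node Type and Trial
    fixed effects and participant random effects.
    """
    df, coding = encode_predictors(table, spec)
    out = {}
    for condition in spec.conditions:
        sub = df[df["condition"] == condition]
        if sub["participant"].nunique() < 2:
            raise ValueError(
                f"need >= 2 participants in condition {condition!r}")
        cond_spec = ModelSpec(name=f"{spec.name}:{condition}",
                              conditions=(condition,),
                              include_priming=spec.include_priming,
                              node_types=spec.node_types,
                              re_terms=re_terms, reml=spec.reml)
        out[condition] = fit_mixed_model(sub, cond_spec, reml=reml,
                                         coding=coding)
    return out


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    """Bias / RMSE / CI coverage / rejection rates over replicate fits."""

    per_term: dict
    n_sims: int
    convergence_rate: float
    alpha: float

    def to_dict(self) -> dict:
        return {"per_term": self.per_term, "n_sims": self.n_sims,
                "convergence_rate": self.convergence_rate,
                "alpha": self.alpha}


def _recovery_truth(params: GenerativeParams, conditions: tuple,
                    include_priming: bool) -> dict:
    s = [params.surprisal_effect[c] for c in conditions]
    truth = {
        "NodeType": (s[0] + s[1]) / 2.0,
        "NodeType:Condition": (s[1] - s[0]) / 2.0,
        "Trial": params.trial_slope_mean,
    }
    if include_priming:
        truth["Lag10"] = params.lag10_effect
        truth["Recency"] = params.recency_effect
    return truth


def parameter_recovery(params: GenerativeParams, n_sims: int,
                       seed: int | None = None,
                       conditions: tuple = ("random", "hamiltonian"),
                       include_priming: bool = True,
                       re_terms: tuple = ("intercept", "trial", "node_type"),
                       alpha: float = 0.05,
                       rt_floor: float = 100.0, sd_cutoff: float = 3.0,
                       subject_loss_threshold: float = 0.5) -> RecoveryReport:
    """Repeated simulate -> exclude -> fit cycles against known truth.

    Each replicate simulates a full two-condition experiment from ``params``,
    applies the exclusion cascade, and fits the (priming) mixed model whose
    random-effects structure matches the generator.  Reports per-term bias,
    relative bias, RMSE, 95% CI coverage and rejection rate, plus the
    overall convergence rate.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    spec = replace(MODEL_SPECS["priming" if include_priming else "model1"],
                   conditions=tuple(conditions), re_terms=tuple(re_terms))
    truth = _recovery_truth(params, tuple(conditions), include_priming)

    root = np.random.default_rng(seed)
    estimates: dict[str, list] = {t: [] for t in truth}
    ses: dict[str, list] = {t: [] for t in truth}
    pvals: dict[str, list] = {t: [] for t in truth}
    crits: dict[str, list] = {t: [] for t in truth}
    converged = []
    for _ in range(n_sims):
        sim_seed = int(root.integers(2 ** 31))
        table = simulate_experiment(params, seed=sim_seed,
                                    conditions=conditions)
        kept, _ = apply_exclusions(table, rt_floor=rt_floor,
                                   sd_cutoff=sd_cutoff,
                                   subject_loss_threshold=subject_loss_threshold)
        df, coding = encode_predictors(kept, spec)
        fit = fit_mixed_model(df, spec, coding=coding)
        converged.append(fit.converged)
        if not fit.converged:
            continue
        for term in truth:
            estimates[term].append(fit[term])
            ses[term].append(fit.se(term))
            pvals[term].append(float(fit.pvalues[term]))
            crits[term].append(
                float(stats.t.ppf(1 - alpha / 2, fit.df_terms[term])))

    per_term = {}
    for term, tv in truth.items():
        est = np.asarray(estimates[term])
        se = np.asarray(ses[term])
        p = np.asarray(pvals[term])
        crit = np.asarray(crits[term])
        bias = float(est.mean() - tv) if len(est) else float("nan")
        per_term[term] = {
            "truth": tv,
            "mean_estimate": float(est.mean()) if len(est) else float("nan"),
            "bias": bias,
            "relative_bias": bias / tv if tv != 0 else float("nan"),
            "rmse": float(np.sqrt(((est - tv) ** 2).mean())) if len(est)
                    else float("nan"),
            "coverage": float((np.abs(est - tv) <= crit * se).mean())
                        if len(est) else float("nan"),
            "rejection_rate": float((p < alpha).mean()) if len(p)
                              else float("nan"),
        }
    return RecoveryReport(per_term=per_term, n_sims=n_sims,
                          convergence_rate=float(np.mean(converged)),
                          alpha=alpha)
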