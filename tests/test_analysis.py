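import subprocess
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from commwalk import (GenerativeParams, a_prime, apply_exclusions,
                      cover_task_summary, encode_predictors, fit_mixed_model,
                      fit_priming_model, likelihood_ratio_test,
                      parameter_recovery, simple_effects,
                      simulate_experiment, surprisal_summary)
from commwalk.analysis import MODEL_SPECS, ModelSpec, UnusableDataError


def exclusion_fixture_100():
    """One participant, 100 rows engineered for exact per-stage counts:
    9 incorrect -> 11 rotated -> 3 implausibly fast (50/80/99 ms, with one
    row at exactly 100 ms that must survive) -> 2 extreme outliers (5000 ms,
    z > 3 against the 77 remaining rows)."""
    rows = []
    rows += [dict(correct=False, rotated=False, rt=500.0)] * 9
    rows += [dict(correct=True, rotated=True, rt=500.0)] * 11
    rows += [dict(correct=True, rotated=False, rt=rt)
             for rt in (50.0, 80.0, 99.0)]
    rows += [dict(correct=True, rotated=False, rt=100.0)]
    rows += [dict(correct=True, rotated=False, rt=5000.0)] * 2
    rows += [dict(correct=True, rotated=False, rt=rt)
             for rt in np.linspace(480, 520, 74)]
    df = pd.DataFrame(rows)
    df.insert(0, "participant", "A")
    assert len(df) == 100
    return df


class TestExclusionCascade:
    def test_stage_counts_match_fixture_design(self):
        kept, report = apply_exclusions(exclusion_fixture_100())
        assert report.removed("incorrect") == 9
        assert report.removed("rotated") == 11
        assert report.removed("implausible_rt") == 3
        assert report.removed("outlier_3sd") == 2
        assert report.removed("subject_level") == 0
        assert report.n_input == 100 and report.n_output == 75

    def test_rt_exactly_100_survives_strict_floor(self):
        kept, _ = apply_exclusions(exclusion_fixture_100())
        assert (kept["rt"] == 100.0).sum() == 1

    def test_fractions_relative_to_pre_stage_counts(self):
        _, report = apply_exclusions(exclusion_fixture_100())
        stage = {s["stage"]: s for s in report.stages}
        assert stage["incorrect"]["fraction"] == 9 / 100
        assert stage["rotated"]["fraction"] == 11 / 91
        assert stage["implausible_rt"]["fraction"] == 3 / 80

    def test_anomalous_subject_dropped_at_final_stage(self):
        df = exclusion_fixture_100()
        bad = pd.DataFrame(
            [dict(participant="B", correct=False, rotated=False, rt=500.0)] * 48
            + [dict(participant="B", correct=True, rotated=False, rt=500.0)] * 2)
        kept, report = apply_exclusions(pd.concat([df, bad],
                                                  ignore_index=True))
        assert report.dropped_subjects == ["B"]
        assert report.removed("subject_level") == 2
        assert set(kept["participant"]) == {"A"}
        assert report.subject_retained_fraction["B"] == 2 / 50

    def test_empty_result_signalled(self):
        df = exclusion_fixture_100()
        df["correct"] = False
        with pytest.raises(UnusableDataError):
            apply_exclusions(df)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            apply_exclusions(pd.DataFrame({"rt": [1.0]}))


class TestAPrime:
    def test_chance_and_perfect(self):
        assert a_prime(0.3, 0.3) == 0.5
        assert a_prime(1.0, 0.0) == 1.0

    def test_hand_computed_value(self):
        # 0.5 + (0.8 * 1.8) / (4 * 0.9 * 0.9)
        assert a_prime(0.9, 0.1) == pytest.approx(0.9444444444444444,
                                                  rel=1e-12)

    def test_complement_symmetry(self):
        for h, f in [(0.9, 0.1), (0.7, 0.4), (0.2, 0.6)]:
            assert a_prime(h, f) + a_prime(f, h) == pytest.approx(1.0)

    def test_dominates_single_point_trapezoid_auc(self):
        # the trapezoidal AUC through (F, H) is a lower bound, tight at
        # chance and at perfect sensitivity
        for h in np.linspace(0, 1, 11):
            for f in np.linspace(0, 1, 11):
                if h >= f:
                    trapezoid = (1 + h - f) / 2
                    assert a_prime(h, f) >= trapezoid - 1e-12
        assert a_prime(0.5, 0.5) == (1 + 0.0) / 2
        assert a_prime(1.0, 0.0) == (1 + 1.0) / 2

    def test_invalid_rates(self):
        with pytest.raises(ValueError):
            a_prime(1.2, 0.0)


class TestCoverSummary:
    def test_hand_built_rates(self):
        rows = ([dict(participant="p1", rotated=True, response="rotated")] * 2
                + [dict(participant="p1", rotated=False,
                        response="canonical")] * 7
                + [dict(participant="p1", rotated=False,
                        response="rotated")] * 1)
        summary = cover_task_summary(pd.DataFrame(rows))
        row = summary.per_participant.iloc[0]
        assert row["hit_rate"] == 1.0
        assert row["false_alarm_rate"] == 0.125
        assert row["a_prime"] == a_prime(1.0, 0.125)

    def test_empty_cell_continuity_correction(self):
        rows = [dict(participant="p1", rotated=False,
                     response="canonical")] * 5
        summary = cover_task_summary(pd.DataFrame(rows))
        assert summary.per_participant.iloc[0]["hit_rate"] == 0.5

    def test_group_test_against_chance(self):
        p = GenerativeParams(n_participants=4)
        table = simulate_experiment(p, seed=30, conditions=("random",))
        summary = cover_task_summary(table)
        assert 0.5 < summary.mean_a_prime <= 1.0
        assert summary.t_statistic > 0
        assert summary.df == 3


class TestSurprisalSummary:
    def test_hand_built_difference(self):
        rows = [
            dict(participant="x", condition="random",
                 node_type="pre_transition", rt=300.0),
            dict(participant="x", condition="random",
                 node_type="transition", rt=320.0),
            dict(participant="x", condition="random",
                 node_type="pre_transition", rt=310.0),
            dict(participant="x", condition="random",
                 node_type="transition", rt=330.0),
            dict(participant="x", condition="random",
                 node_type="other", rt=999.0),
        ]
        out = surprisal_summary(pd.DataFrame(rows))
        assert len(out) == 1
        assert out.iloc[0]["pre_transition_mean"] == 305.0
        assert out.iloc[0]["transition_mean"] == 325.0
        assert out.iloc[0]["difference"] == 20.0

    def test_participant_missing_a_type_is_skipped(self):
        rows = [dict(participant="x", condition="random",
                     node_type="pre_transition", rt=300.0),
                dict(participant="x", condition="random",
                     node_type="transition", rt=320.0),
                dict(participant="y", condition="random",
                     node_type="pre_transition", rt=400.0)]
        with pytest.warns(UserWarning):
            out = surprisal_summary(pd.DataFrame(rows))
        assert list(out["participant"]) == ["x"]

    def test_no_boundary_trials_rejected(self):
        rows = [dict(participant="x", condition="random",
                     node_type="other", rt=1.0)]
        with pytest.raises(UnusableDataError):
            surprisal_summary(pd.DataFrame(rows))


@pytest.fixture(scope="module")
def small_table():
    params = replace(GenerativeParams(), n_participants=6,
                     residual_family="gaussian")
    table = simulate_experiment(params, seed=31,
                                conditions=("random", "hamiltonian"))
    kept, _ = apply_exclusions(table)
    return kept


class TestEncoding:
    def test_trial_standardized_and_conditions_coded(self, small_table):
        df, coding = encode_predictors(small_table, MODEL_SPECS["model1"])
        assert abs(df["trial_std"].mean()) < 1e-9
        assert df["trial_std"].std(ddof=0) == pytest.approx(1.0)
        assert set(df["condcode"]) == {-1.0, 1.0}
        assert set(df["nodecode"]) == {-0.5, 0.5}
        assert coding["condition"] == {"random": -1.0, "hamiltonian": 1.0}

    def test_centering_leaves_cell_means_unchanged(self, small_table):
        df, _ = encode_predictors(small_table, MODEL_SPECS["model1"])
        raw = small_table[small_table["node_type"].isin(
            ["pre_transition", "transition"])]
        assert df["rt"].mean() == pytest.approx(raw["rt"].mean())

    def test_priming_rows_drop_missing_recency(self, small_table):
        df, _ = encode_predictors(small_table, MODEL_SPECS["priming"])
        assert df["recency"].notna().all()

    def test_unknown_condition_rejected(self, small_table):
        spec = ModelSpec("bogus", ("random", "martian"))
        with pytest.raises(ValueError):
            encode_predictors(small_table, spec)

    def test_unknown_node_type_rejected(self, small_table):
        broken = small_table.copy()
        broken.loc[broken.index[0], "node_type"] = "weird"
        spec = replace(MODEL_SPECS["model1"], node_types="all")
        with pytest.raises(ValueError):
            encode_predictors(broken, spec)


class TestMixedModel:
    def test_estimates_near_generating_values(self, small_table):
        spec = replace(MODEL_SPECS["model1"],
                       re_terms=("intercept", "trial", "node_type"))
        df, coding = encode_predictors(small_table, spec)
        fit = fit_mixed_model(df, spec, coding=coding)
        assert fit.converged
        truth = {"Trial": -31.0, "NodeType:Condition": -8.5}
        for term, tv in truth.items():
            assert abs(fit[term] - tv) < 4 * fit.se(term)

    def test_ladder_recorded_and_df_method_set(self, small_table):
        spec = MODEL_SPECS["model1"]
        df, _ = encode_predictors(small_table, spec)
        fit = fit_mixed_model(df, spec)
        assert fit.re_terms[0] == "intercept"
        assert fit.df_method == "between-within containment"
        # group-level terms get participant-limited df, priming-free model
        assert fit.df_terms["Trial"] < 20
        assert np.isfinite(fit.llf)

    def test_boundary_variance_flagged_singular(self):
        params = replace(GenerativeParams(), n_participants=8,
                         trial_slope_sd=0.0, surprisal_effect_sd=0.0,
                         residual_family="gaussian")
        table = simulate_experiment(params, seed=32,
                                    conditions=("random", "hamiltonian"))
        kept, _ = apply_exclusions(table)
        spec = replace(MODEL_SPECS["model1"],
                       re_terms=("intercept", "trial", "node_type"))
        df, _ = encode_predictors(kept, spec)
        fit = fit_mixed_model(df, spec)
        assert fit.singular

    def test_requires_two_participants(self, small_table):
        spec = MODEL_SPECS["model1"]
        df, _ = encode_predictors(small_table, spec)
        one = df[df["participant"] == df["participant"].iloc[0]]
        with pytest.raises(ValueError):
            fit_mixed_model(one, spec)


class TestModelComparison:
    def test_lrt_on_nested_ml_fits(self, small_table):
        full_spec = MODEL_SPECS["priming"]
        red_spec = MODEL_SPECS["priming_reduced"]
        df, coding = encode_predictors(small_table, full_spec)
        full = fit_mixed_model(df, full_spec, reml=False, coding=coding)
        reduced = fit_mixed_model(df, red_spec, reml=False, coding=coding)
        assert full.llf >= reduced.llf - 1e-6   # guards optimizer failures
        lrt = likelihood_ratio_test(full, reduced)
        assert lrt.statistic >= 0.0
        assert lrt.df == 6   # NodeType, Condition and their 4 interactions
        assert 0.0 <= lrt.p_value <= 1.0

    def test_reml_fits_rejected(self, small_table):
        full_spec = MODEL_SPECS["priming"]
        df, _ = encode_predictors(small_table, full_spec)
        full = fit_mixed_model(df, full_spec, reml=True)
        with pytest.raises(ValueError):
            likelihood_ratio_test(full, full)

    def test_non_nested_rejected(self, small_table):
        full_spec = MODEL_SPECS["priming"]
        red_spec = MODEL_SPECS["priming_reduced"]
        df, _ = encode_predictors(small_table, full_spec)
        full = fit_mixed_model(df, full_spec, reml=False)
        reduced = fit_mixed_model(df, red_spec, reml=False)
        with pytest.raises(ValueError):
            likelihood_ratio_test(reduced, full)


class TestSimpleEffects:
    def test_per_condition_fits(self, small_table):
        spec = replace(MODEL_SPECS["model1"],
                       re_terms=("intercept", "trial", "node_type"))
        fits = simple_effects(small_table, spec)
        assert set(fits) == {"random", "hamiltonian"}
        for fit in fits.values():
            assert list(fit.terms) == ["Intercept", "NodeType", "Trial",
                                       "NodeType:Trial"]
            assert fit.converged


class TestAgainstLme4:
    def test_fixed_effects_match_lmer(self, small_table, tmp_path):
        """Independent oracle: the same random-intercept model fit by lme4."""
        spec = replace(MODEL_SPECS["model1"], re_terms=("intercept",))
        df, _ = encode_predictors(small_table, spec)
        csv = tmp_path / "encoded.csv"
        df[["rt", "participant", "nodecode", "condcode",
            "trial_std"]].to_csv(csv, index=False)
        out = tmp_path / "fixef.csv"
        rscript = tmp_path / "fit.R"
        rscript.write_text(f"""
suppressMessages(library(lme4))
d <- read.csv("{csv}")
m <- lmer(rt ~ nodecode * condcode * trial_std + (1 | participant),
          data = d, REML = TRUE)
write.csv(data.frame(term = names(fixef(m)), beta = fixef(m)),
          "{out}", row.names = FALSE)
""")
        subprocess.run(["Rscript", str(rscript)], check=True,
                       capture_output=True)
        r = pd.read_csv(out).set_index("term")["beta"]
        fit = fit_mixed_model(df, spec)
        mapping = {
            "Intercept": "(Intercept)", "NodeType": "nodecode",
            "Condition": "condcode", "Trial": "trial_std",
            "NodeType:Condition": "nodecode:condcode",
            "NodeType:Trial": "nodecode:trial_std",
            "Condition:Trial": "condcode:trial_std",
            "NodeType:Condition:Trial": "nodecode:condcode:trial_std",
        }
        for ours, theirs in mapping.items():
            assert fit[ours] == pytest.approx(r[theirs], rel=1e-3, abs=0.02)


class TestRecoveryReport:
    def test_report_structure(self):
        params = replace(GenerativeParams(), n_participants=4,
                         residual_family="gaussian")
        report = parameter_recovery(params, n_sims=2, seed=33)
        assert report.n_sims == 2
        assert 0.0 <= report.convergence_rate <= 1.0
        for term in ("NodeType", "NodeType:Condition", "Trial",
                     "Lag10", "Recency"):
            stats = report.per_term[term]
            assert {"truth", "bias", "rmse", "coverage",
                    "rejection_rate"} <= set(stats)
        d = report.to_dict()
        assert d["alpha"] == 0.05
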