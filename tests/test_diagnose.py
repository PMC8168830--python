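import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from mimosa import (
    StudyTable,
    StudyTableError,
    Variable,
    compare_by_completeness,
    predictors_of_missingness,
    summarize_missingness,
)


class TestSummarizeMissingness:
    def test_toy_counts_by_hand(self, toy_table):
        s = summarize_missingness(toy_table)
        assert s.per_variable.loc["score", "n_missing"] == 1
        assert s.per_variable.loc["smoke", "n_missing"] == 2
        assert s.n_complete == 2 and s.n_records == 4
        assert len(s.pattern_table) == 3
        assert sorted(s.pattern_table["count"]) == [1, 1, 2]
        # the all-observed pattern count equals the complete-record count
        top = s.pattern_table.iloc[0]
        assert all(top[v] for v in s.analysis_variables) and top["count"] == 2

    def test_fully_observed_table(self, toy_table):
        full = StudyTable(
            toy_table.data.fillna(1.0), list(toy_table.variables.values())
        )
        s = summarize_missingness(full)
        assert (s.per_variable["prop_missing"] == 0).all()
        assert len(s.pattern_table) == 1
        assert s.complete_proportion == 1.0

    def test_row_permutation_invariance(self, preset_small):
        table, _, _ = preset_small
        s1 = summarize_missingness(table)
        shuffled = StudyTable(
            table.data.sample(frac=1, random_state=0).reset_index(drop=True),
            list(table.variables.values()),
        )
        s2 = summarize_missingness(shuffled)
        assert s1.n_complete == s2.n_complete
        pd.testing.assert_frame_equal(s1.per_variable, s2.per_variable)

    def test_empty_table_rejected(self, toy_table):
        empty = StudyTable(toy_table.data.iloc[:0], list(toy_table.variables.values()))
        with pytest.raises(StudyTableError):
            summarize_missingness(empty)

    def test_preset_complete_proportion_matches_calibration(self, preset_large):
        table, _, _ = preset_large
        s = summarize_missingness(table)
        assert 0.18 <= s.complete_proportion <= 0.28
        # auxiliaries are excluded from the complete-record definition
        assert set(s.analysis_variables) == {
            table.outcome, table.exposure, *table.confounders
        }


class TestCompareByCompleteness:
    def test_forced_group_prevalences(self):
        data = pd.DataFrame(
            {
                "y": [1.0, 2.0, np.nan, np.nan],
                "x": [0.0, 0.0, 1.0, 1.0],
            }
        )
        t = StudyTable(
            data,
            [Variable("y", "outcome", "continuous"), Variable("x", "exposure", "binary")],
        )
        comp = compare_by_completeness(t)
        row = comp[(comp.variable == "x") & (comp.level == 1.0)].iloc[0]
        assert row["complete_spread"] == 0.0  # 0% exposed among complete
        assert row["incomplete_spread"] == 100.0

    def test_fully_missing_cell_is_not_estimable(self):
        data = pd.DataFrame(
            {
                "y": [1.0, 2.0, np.nan, np.nan],
                "x": [0.0, 1.0, np.nan, np.nan],
            }
        )
        t = StudyTable(
            data,
            [Variable("y", "outcome", "continuous"), Variable("x", "exposure", "binary")],
        )
        comp = compare_by_completeness(t)
        row = comp[(comp.variable == "y")].iloc[0]
        assert np.isnan(row["incomplete_value"])  # NaN, never zero

    def test_single_group_flagged_not_failed(self, toy_table):
        full = StudyTable(toy_table.data.fillna(1.0), list(toy_table.variables.values()))
        comp = compare_by_completeness(full)
        assert comp.attrs["single_group_warning"]

    def test_outcome_higher_among_complete_records(self, preset_large):
        """Missingness rises with lower attainment, so completers score higher."""
        table, _, _ = preset_large
        comp = compare_by_completeness(table)
        row = comp[comp.variable == table.outcome].iloc[0]
        assert row["complete_value"] > row["incomplete_value"]


class TestPredictorsOfMissingness:
    def test_recovers_known_selection_model_vs_independent_optimizer(self):
        """Completeness ~ expit(-1 + x): MLE near truth and near a brute-force fit."""
        rng = np.random.default_rng(0)
        n = 50000
        x = rng.standard_normal(n)
        complete = rng.random(n) < expit(-1.0 + x)
        data = pd.DataFrame(
            {
                "y": np.where(complete, rng.standard_normal(n), np.nan),
                "e": rng.binomial(1, 0.5, n).astype(float),
                "x": x,
            }
        )
        t = StudyTable(
            data,
            [
                Variable("y", "outcome", "continuous"),
                Variable("e", "exposure", "binary"),
                Variable("x", "confounder", "continuous"),
            ],
        )
        model = predictors_of_missingness(t, ["x"])
        assert model.converged
        coef = model.coefficient("x")["coef"]
        assert 0.9 <= coef <= 1.1

        # independent oracle: direct likelihood maximization with scipy
        yi = complete.astype(float)
        X = np.column_stack([np.ones(n), x])

        def nll(beta):
            eta = X @ beta
            return -(yi * eta - np.logaddexp(0.0, eta)).sum()

        brute = minimize(nll, np.zeros(2), method="BFGS").x
        assert abs(coef - brute[1]) < 1e-3
        assert model.coefficient("x")["odds_ratio"] == pytest.approx(np.exp(coef))

    def test_constant_predictor_flagged_degenerate(self, toy_table):
        model = predictors_of_missingness(toy_table, ["sex", "score"])
        # 'score' has missing values -> rows dropped; make a truly constant one
        data = toy_table.data.assign(sex=1.0)
        t = StudyTable(data, list(toy_table.variables.values()))
        model = predictors_of_missingness(t, ["sex"])
        assert not model.converged
        assert any("degenerate" in w for w in model.warnings)

    def test_mcar_preset_shows_no_association(self):
        """Under MCAR the joint LR test should almost never reject."""
        from scipy.special import logit
        from mimosa import MissingnessMechanism, VariableMechanism, impose_missingness
        from mimosa.synthgen import _preset_config, generate_cohort

        rejections = 0
        for seed in range(10):
            table = generate_cohort(_preset_config(2000, seed=seed))
            mech = MissingnessMechanism(
                {"smoking_14": VariableMechanism(float(logit(0.5)))}
            )
            out = impose_missingness(table, mech, seed=seed)
            model = predictors_of_missingness(
                out, ["sex", "mat_smoking", "mat_education_high"]
            )
            if model.lr_pvalue < 0.01:
                rejections += 1
        assert rejections <= 1

    def test_preset_recovers_mechanism_coefficient_direction(self, preset_large):
        table, _, mech = preset_large
        model = predictors_of_missingness(
            table, ["sex", "mat_smoking", "mat_education_high"]
        )
        # higher maternal education -> less missingness everywhere -> more complete
        assert model.coefficient("mat_education_high")["coef"] > 0
        assert model.coefficient("mat_education_high")["p"] < 0.05
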