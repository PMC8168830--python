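import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from mimosa import (
    DegenerateTargetError,
    ImputationSpec,
    ImputedStack,
    StudyTable,
    StudyTableError,
    Variable,
    default_spec,
    impute_bayes_linear,
    impute_bayes_logistic,
    impute_pmm,
    initialize,
    run_chained,
)
from mimosa.synthgen import substream


def rng_pair(seed=123):
    """Two generators on the same stream, for common-random-number contracts."""
    return substream(seed, "test"), substream(seed, "test")


class TestInitialize:
    def test_single_valued_donor_pool(self):
        data = pd.DataFrame(
            {
                "y": [1.0, 1.0, 1.0, np.nan, np.nan],
                "x": [0.0, 1.0, 0.0, 1.0, 0.0],
            }
        )
        t = StudyTable(
            data,
            [Variable("y", "outcome", "continuous"), Variable("x", "exposure", "binary")],
        )
        filled = initialize(t, seed=0)
        assert (filled["y"] == 1.0).all()

    def test_requires_missing_cells(self):
        data = pd.DataFrame({"y": [1.0], "x": [0.0]})
        t = StudyTable(
            data,
            [Variable("y", "outcome", "continuous"), Variable("x", "exposure", "binary")],
        )
        with pytest.raises(StudyTableError):
            initialize(t, seed=0)

    def test_initialized_marginal_matches_observed(self):
        rng = np.random.default_rng(1)
        n = 20000
        y = rng.normal(10, 2, n)
        data = pd.DataFrame({"y": y, "x": rng.binomial(1, 0.5, n).astype(float)})
        data.loc[rng.random(n) < 0.5, "y"] = np.nan
        t = StudyTable(
            data,
            [Variable("y", "outcome", "continuous"), Variable("x", "exposure", "binary")],
        )
        filled = initialize(t, seed=3)
        observed = data["y"].dropna()
        imputed = filled.loc[data["y"].isna(), "y"]
        assert abs(imputed.mean() - observed.mean()) < 0.1
        assert abs(imputed.std() - observed.std()) < 0.1


class TestBayesLinear:
    def test_offset_is_exactly_additive_under_common_randomness(self):
        rng = np.random.default_rng(7)
        X_obs = np.column_stack([np.ones(50), rng.standard_normal(50)])
        y = X_obs @ np.array([1.0, 2.0]) + rng.standard_normal(50)
        X_mis = np.column_stack([np.ones(10), rng.standard_normal(10)])
        r1, r2 = rng_pair()
        base = impute_bayes_linear(y, X_obs, X_mis, 0.0, r1)
        shifted = impute_bayes_linear(y, X_obs, X_mis, 5.0, r2)
        np.testing.assert_array_equal(shifted, base + 5.0)

    def test_degenerate_noise_limit_reproduces_exact_line(self):
        x = np.arange(10, dtype=float)
        X_obs = np.column_stack([np.ones(10), x])
        y = 2.0 + 3.0 * x  # exactly linear, zero residual
        X_mis = np.array([[1.0, 20.0], [1.0, -4.0]])
        out = impute_bayes_linear(y, X_obs, X_mis, 0.0, substream(0, "t"))
        np.testing.assert_allclose(out, [62.0, -10.0], atol=1e-8)

    def test_posterior_concentrates_at_truth(self):
        """y ~ N(2 + 3x, 1): imputations at x=1 average to 5 at large n."""
        rng = np.random.default_rng(2)
        n = 10000
        x = rng.standard_normal(n)
        y = 2.0 + 3.0 * x + rng.standard_normal(n)
        X_obs = np.column_stack([np.ones(n), x])
        X_mis = np.tile([1.0, 1.0], (2000, 1))
        draws = impute_bayes_linear(y, X_obs, X_mis, 0.0, substream(5, "t"))
        assert 4.9 <= draws.mean() <= 5.1

    def test_too_few_rows_rejected(self):
        X = np.ones((3, 2))
        with pytest.raises(StudyTableError, match="observed rows"):
            impute_bayes_linear(np.ones(3), X, X, 0.0, substream(0, "t"))

    def test_rank_deficiency_falls_back_with_warning(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(30)
        X_obs = np.column_stack([np.ones(30), x, x])  # duplicated column
        y = x + rng.standard_normal(30)
        warnings = []
        out = impute_bayes_linear(y, X_obs, X_obs[:5], 0.0, substream(1, "t"), warnings)
        assert np.isfinite(out).all()
        assert any("ridge" in w for w in warnings)


class TestBayesLogistic:
    def test_large_offset_forces_ones(self):
        rng = np.random.default_rng(4)
        n = 500
        x = rng.standard_normal(n)
        y = (rng.random(n) < expit(x)).astype(float)
        X = np.column_stack([np.ones(n), x])
        out = impute_bayes_logistic(y, X, X, 50.0, substream(2, "t"))
        assert (out == 1.0).all()

    def test_zero_offset_preserves_prevalence(self):
        rng = np.random.default_rng(9)
        n = 20000
        y = rng.binomial(1, 0.3, n).astype(float)
        X = np.ones((n, 1))
        out = impute_bayes_logistic(y, X, np.ones((5000, 1)), 0.0, substream(3, "t"))
        assert 0.27 <= out.mean() <= 0.33

    def test_one_class_target_rejected(self):
        X = np.ones((20, 1))
        with pytest.raises(DegenerateTargetError):
            impute_bayes_logistic(np.ones(20), X, X, 0.0, substream(0, "t"))

    def test_separation_triggers_penalized_fallback(self):
        x = np.concatenate([-np.ones(20), np.ones(20)])
        y = (x > 0).astype(float)  # perfectly separated
        X = np.column_stack([np.ones(40), x])
        warnings = []
        out = impute_bayes_logistic(y, X, X, 0.0, substream(1, "t"), warnings)
        assert any("separation" in w for w in warnings)
        assert set(np.unique(out)) <= {0.0, 1.0}


class TestPmm:
    def test_unique_nearest_donor_is_copied(self):
        # exactly linear target: zero residual, so predictions are exact and
        # the missing row's mean coincides with one observed row's
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        X_obs = np.column_stack([np.ones(5), x])
        y = 2.0 * x
        out = impute_pmm(y, X_obs, np.array([[1.0, 2.0]]), 1, substream(0, "t"))
        assert out[0] == 4.0

    def test_prediction_ties_break_at_lowest_row_index(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        X_obs = np.column_stack([np.ones(4), x])
        y = np.array([7.0, 8.0, 9.0, 10.0])
        # constant-only design: every donor has the same predicted mean
        ones = np.ones((4, 1))
        out = impute_pmm(y, ones, np.array([[1.0]]), 1, substream(0, "t"))
        assert out[0] == 7.0

    def test_imputed_values_are_donor_pool_members(self):
        rng = np.random.default_rng(11)
        n = 300
        x = rng.standard_normal(n)
        y = x + rng.standard_normal(n)
        X_obs = np.column_stack([np.ones(n), x])
        X_mis = np.column_stack([np.ones(50), rng.standard_normal(50)])
        out = impute_pmm(y, X_obs, X_mis, 5, substream(4, "t"))
        assert np.isin(out, y).all()

    def test_k_larger_than_pool_rejected(self):
        X = np.ones((4, 1))
        with pytest.raises(StudyTableError, match="exceeds"):
            impute_pmm(np.ones(4), X, X, 9, substream(0, "t"))

    def test_pmm_accuracy_comparable_to_bayes_linear(self):
        """Replicate-averaged imputation MSE within 10% of the linear draw."""
        mse_pmm, mse_lin = [], []
        for rep in range(40):
            rng = np.random.default_rng(100 + rep)
            n, n_mis = 2000, 400
            x = rng.standard_normal(n + n_mis)
            y = x + rng.standard_normal(n + n_mis)
            X = np.column_stack([np.ones(n + n_mis), x])
            y_obs, X_obs = y[:n], X[:n]
            y_true, X_mis = y[n:], X[n:]
            p = impute_pmm(y_obs, X_obs, X_mis, 5, substream(rep, "pmm"))
            l = impute_bayes_linear(y_obs, X_obs, X_mis, 0.0, substream(rep, "lin"))
            mse_pmm.append(np.mean((p - y_true) ** 2))
            mse_lin.append(np.mean((l - y_true) ** 2))
        ratio = np.mean(mse_pmm) / np.mean(mse_lin)
        assert 0.9 <= ratio <= 1.1


class TestRunChained:
    def test_same_seed_bit_identical_different_seed_differs(self, preset_small):
        table, _, _ = preset_small
        spec = default_spec(table, m=3, cycles=3, seed=1)
        a = run_chained(table, spec)
        b = run_chained(table, spec)
        for i in range(3):
            pd.testing.assert_frame_equal(a.tables[i], b.tables[i])
        c = run_chained(table, default_spec(table, m=3, cycles=3, seed=2))
        assert not a.tables[0].equals(c.tables[0])

    def test_observed_cells_preserved_bit_exactly(self, preset_small):
        table, _, _ = preset_small
        spec = default_spec(table, m=2, cycles=2, seed=3)
        stack = run_chained(table, spec)
        observed = table.mask
        for t in stack.tables:
            for col in table.data.columns:
                keep = observed[col]
                assert (
                    t.loc[keep, col].to_numpy() == table.data.loc[keep, col].to_numpy()
                ).all()

    def test_no_missing_cells_in_any_copy(self, preset_small):
        table, _, _ = preset_small
        stack = run_chained(table, default_spec(table, m=2, cycles=2, seed=4))
        for t in stack.tables:
            assert not t.isna().any().any()
            assert set(t[table.exposure].unique()) <= {0.0, 1.0}

    def test_between_imputation_variance_positive(self, preset_small):
        from mimosa import SubstantiveModelSpec, fit_stack, pool_rubin

        table, _, _ = preset_small
        stack = run_chained(table, default_spec(table, m=5, cycles=4, seed=5))
        pooled = pool_rubin(fit_stack(stack, SubstantiveModelSpec.from_table(table)))
        assert pooled.between_variance > 0
        assert pooled.total_variance >= pooled.within_variance

    def test_single_incomplete_continuous_offset_shifts_exactly(
        self, single_missing_table
    ):
        """With one incomplete variable there is no feedback: δ adds exactly."""
        t = single_missing_table
        spec0 = default_spec(t, m=2, cycles=3, seed=6)
        spec5 = default_spec(t, m=2, cycles=3, seed=6, offsets={"y": 5.0})
        s0 = run_chained(t, spec0)
        s5 = run_chained(t, spec5)
        mis = t.data["y"].isna()
        for i in range(2):
            np.testing.assert_allclose(
                s5.tables[i].loc[mis, "y"],
                s0.tables[i].loc[mis, "y"] + 5.0,
                rtol=0,
                atol=1e-12,
            )

    def test_polytomous_imputes_declared_levels(self):
        rng = np.random.default_rng(8)
        n = 400
        g = rng.choice(["a", "b", "c"], n, p=[0.5, 0.3, 0.2])
        y = rng.standard_normal(n) + (g == "c") * 2.0
        data = pd.DataFrame(
            {"y": y, "x": rng.binomial(1, 0.4, n).astype(float), "g": g}
        )
        data.loc[rng.random(n) < 0.3, "g"] = np.nan
        t = StudyTable(
            data,
            [
                Variable("y", "outcome", "continuous"),
                Variable("x", "exposure", "binary"),
                Variable("g", "confounder", "categorical", levels=("a", "b", "c")),
            ],
        )
        stack = run_chained(t, default_spec(t, m=2, cycles=3, seed=7))
        for tab in stack.tables:
            assert set(tab["g"].unique()) <= {"a", "b", "c"}

    def test_spec_validation_catches_incompatibility(self, preset_small):
        table, _, _ = preset_small
        spec = default_spec(table, m=2, cycles=2, seed=0)
        bad = ImputationSpec(
            column_models=spec.column_models,
            predictors={**spec.predictors, "smoking_14": ("sex",)},
            m=2,
            substantive_variables=spec.substantive_variables,
        )
        with pytest.raises(StudyTableError, match="incompatible"):
            bad.validate(table)
        with pytest.raises(StudyTableError, match="itself"):
            ImputationSpec(
                column_models=spec.column_models,
                predictors={**spec.predictors, "smoking_14": ("smoking_14",)},
                m=2,
            ).validate(table)
        with pytest.raises(StudyTableError, match="m must be"):
            ImputationSpec(
                column_models=spec.column_models, predictors=spec.predictors, m=1
            ).validate(table)

    def test_stack_serialization_round_trips_losslessly(self, preset_small, tmp_path):
        table, _, _ = preset_small
        stack = run_chained(table, default_spec(table, m=2, cycles=2, seed=8))
        stack.to_dir(tmp_path / "stack")
        back = ImputedStack.from_dir(tmp_path / "stack")
        assert back.m == stack.m
        assert back.spec == stack.spec
        for i in range(stack.m):
            pd.testing.assert_frame_equal(back.tables[i], stack.tables[i])
        pd.testing.assert_frame_equal(
            back.imputed_mask.astype(bool), stack.imputed_mask.astype(bool)
        )
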