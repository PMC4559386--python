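import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from tempodisc import (
    CohortConfig,
    compare_groups,
    delta_r2_f_test,
    em_impute,
    fit_model_hierarchy,
    generate_cohort,
    holm_bonferroni,
    median_split_summary,
    memory_covariate_correlations,
)
from tempodisc.inference import HierarchicalInteractionOLS, build_design, MODEL_TERMS


def analysis_table(seed=0, n=58, **config_kwargs):
    cohort = generate_cohort(CohortConfig(n_participants=n, seed=seed, **config_kwargs))
    table = cohort.rename(
        columns={"true_ln_k": "ln_k", "true_beta": "beta", "true_delta": "delta"}
    )
    return em_impute(table)


class TestEmImpute:
    def test_identity_on_complete_data(self):
        table = analysis_table(seed=3, income_missing_rate=0.0)
        out = em_impute(table)
        pd.testing.assert_frame_equal(out, table)

    def test_observed_values_never_altered(self):
        table = analysis_table(seed=4)
        raw = generate_cohort(CohortConfig(n_participants=58, seed=4))
        observed = raw["income"].notna()
        assert np.allclose(
            table.loc[observed, "income"], raw.loc[observed, "income"]
        )

    def test_bivariate_conditional_mean_oracle(self):
        """With one missing income, EM matches regression imputation: the ML
        conditional mean is the complete-case OLS prediction at the row's IQ."""
        rng = np.random.default_rng(11)
        n = 60
        iq = rng.normal(16, 4, n)
        income = 20000 + 900 * iq + rng.normal(0, 3000, n)
        table = pd.DataFrame({"iq": iq, "income": income})
        table.loc[7, "income"] = np.nan
        out = em_impute(table, columns=["iq", "income"])
        complete = table.dropna()
        ols = sm.OLS(
            complete["income"], sm.add_constant(complete["iq"])
        ).fit()
        oracle = float(ols.predict([1.0, table.loc[7, "iq"]])[0])
        assert out.loc[7, "income"] == pytest.approx(oracle, abs=1e-3)

    def test_mcar_mean_recovery(self):
        """10% MCAR missingness: the imputed column mean stays near truth."""
        rng = np.random.default_rng(5)
        n = 400
        base = rng.normal(0, 1, n)
        table = pd.DataFrame(
            {
                "a": base + rng.normal(0, 0.5, n),
                "b": 2 * base + rng.normal(0, 0.5, n) + 1.0,
            }
        )
        miss = rng.random(n) < 0.1
        truth_mean = table["b"].mean()
        table.loc[miss, "b"] = np.nan
        out = em_impute(table, columns=["a", "b"])
        se = out["b"].std() / np.sqrt(n)
        assert abs(out["b"].mean() - truth_mean) < 2 * se

    def test_all_missing_column_rejected(self):
        table = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="entirely missing"):
            em_impute(table, columns=["a", "b"])


class TestHierarchy:
    def test_betas_match_normal_equations(self):
        """Standardized betas equal the closed-form least-squares solution."""
        table = analysis_table(seed=1)
        design = build_design(table)
        y = table["ln_k"].to_numpy()
        y = (y - y.mean()) / y.std(ddof=1)
        results = fit_model_hierarchy(table, "ln_k")
        for result in results:
            X = np.column_stack(
                [np.ones(len(table))] + [design[t] for t in result.predictors]
            )
            beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)
            betas = np.array([result.coefficients[t][0] for t in result.predictors])
            assert np.allclose(betas, beta_oracle[1:], atol=1e-8)

    def test_r2_monotone_across_hierarchy(self):
        for seed in (2, 3):
            results = fit_model_hierarchy(analysis_table(seed=seed), "beta")
            r2 = [r.r2 for r in results]
            assert r2[0] <= r2[1] <= r2[2]
            assert all(r.adj_r2 <= r.r2 for r in results)

    def test_pure_noise_outcome_has_small_r2(self):
        table = analysis_table(seed=6)
        rng = np.random.default_rng(0)
        table["noise"] = rng.normal(size=len(table))
        result = fit_model_hierarchy(table, "noise")[0]
        assert result.r2 < 0.25

    def test_injected_interaction_detected(self):
        """An outcome built from centred IGD-C2 x gender lights up model 3."""
        hits = 0
        for seed in range(10):
            table = analysis_table(seed=seed)
            gender = (table["gender"] == "female").astype(float)
            centred = table["igd_c2"] - table["igd_c2"].mean()
            rng = np.random.default_rng(seed)
            table["y"] = 0.8 * gender * centred + 0.1 * rng.normal(size=len(table))
            result = fit_model_hierarchy(table, "y")[2]
            beta, p = result.coefficients["gender_x_igd_c2"]
            if p < 0.05 and beta > 0:
                hits += 1
        assert hits >= 8

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="need n >"):
            fit_model_hierarchy(analysis_table(seed=0, n=11), "ln_k")


class TestDeltaR2:
    def test_no_improvement_gives_f_zero(self):
        table = analysis_table(seed=9)
        model = HierarchicalInteractionOLS().fit(table, "ln_k")
        full, red = model.result(3), model.result(2)
        same = delta_r2_f_test(full, full_as_reduced(full), n=full.n)
        assert same["F"] == pytest.approx(0.0, abs=1e-10)
        assert same["p"] == pytest.approx(1.0)

    def test_df_structure_at_n58(self):
        """Three added interactions at n=58 with 10 full predictors: F(3, 47)."""
        table = analysis_table(seed=9)
        model = HierarchicalInteractionOLS().fit(table, "ln_k")
        test = model.result(3).delta_r2_test
        assert test["df"] == (3, 47)

    def test_matches_rss_formula(self):
        """The R2-change F equals the residual-sum-of-squares form."""
        table = analysis_table(seed=12)
        design = build_design(table)
        y = table["beta"].to_numpy()
        y = (y - y.mean()) / y.std(ddof=1)
        model = HierarchicalInteractionOLS().fit(table, "beta")
        for mid in (2, 3):
            full, red = model.result(mid), model.result(mid - 1)
            sse = {}
            for r in (full, red):
                X = sm.add_constant(design[r.predictors].to_numpy())
                sse[r.model_id] = float(sm.OLS(y, X).fit().ssr)
            q = len(full.predictors) - len(red.predictors)
            dfden = full.n - len(full.predictors) - 1
            F_oracle = ((sse[red.model_id] - sse[full.model_id]) / q) / (
                sse[full.model_id] / dfden
            )
            assert full.delta_r2_test["F"] == pytest.approx(F_oracle, abs=1e-8)

    def test_non_nested_rejected(self):
        table = analysis_table(seed=9)
        model = HierarchicalInteractionOLS().fit(table, "ln_k")
        with pytest.raises(ValueError, match="nested"):
            delta_r2_f_test(model.result(1), model.result(3), n=58)


def full_as_reduced(result):
    """A copy of a result posing as the reduced model minus one term."""
    import copy

    red = copy.deepcopy(result)
    red.predictors = result.predictors[:-1]
    red.r2 = result.r2
    return red


class TestCompareGroups:
    def make_table(self, male, female):
        return pd.DataFrame(
            {
                "gender": ["male"] * len(male) + ["female"] * len(female),
                "x": np.concatenate([male, female]),
            }
        )

    def test_exchangeable_groups_not_significant(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 1, 56)
        res = compare_groups(self.make_table(vals[:28], vals[28:]), "x")
        assert res.p > 0.05

    def test_normal_shift_detected_by_t_test(self):
        rng = np.random.default_rng(1)
        detected = 0
        for _ in range(20):
            male = rng.normal(0, 1, 28)
            female = rng.normal(1.0, 1, 30)
            res = compare_groups(self.make_table(male, female), "x")
            if res.test_name == "t-test" and res.p < 0.05:
                detected += 1
        assert detected >= 18

    def test_skewed_variable_uses_mann_whitney(self):
        rng = np.random.default_rng(2)
        male = rng.lognormal(10, 1.0, 28)
        female = rng.lognormal(9.5, 1.0, 30)
        res = compare_groups(self.make_table(male, female), "x")
        assert res.test_name == "mann-whitney"

    def test_constant_variable_rejected(self):
        table = self.make_table(np.ones(10), np.arange(10.0))
        with pytest.raises(ValueError, match="constant"):
            compare_groups(table, "x")


class TestHolmAndCorrelations:
    def test_family_of_three_threshold(self):
        """Smallest p of a 3-family is held to alpha/3: p=.018 > .0167 fails."""
        reject, _ = holm_bonferroni([0.018, 0.4, 0.6], alpha=0.05)
        assert not reject.any()
        reject, _ = holm_bonferroni([0.016, 0.4, 0.6], alpha=0.05)
        assert reject[0] and not reject[1:].any()

    def test_holm_matches_brute_force_stepdown(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            m = rng.integers(2, 8)
            p = rng.random(m)
            reject, _ = holm_bonferroni(p, alpha=0.05)
            order = np.argsort(p)
            expected = np.zeros(m, dtype=bool)
            for rank, idx in enumerate(order):
                if p[idx] <= 0.05 / (m - rank):
                    expected[idx] = True
                else:
                    break
            assert np.array_equal(reject, expected)

    def test_correlation_families_and_methods(self):
        table = analysis_table(seed=20)
        corr = memory_covariate_correlations(table)
        assert len(corr) == 9
        assert set(corr["covariate"]) == {"age", "iq", "income"}
        assert corr["method"].isin(["pearson", "spearman"]).all()
        # skewed income should fall back to Spearman
        assert (corr.loc[corr["covariate"] == "income", "method"] == "spearman").all()
        assert (corr["p_holm"] >= corr["p"] - 1e-12).all()

    def test_null_familywise_error_controlled(self):
        """Independent scores: at most ~5% of families reject anything."""
        rng = np.random.default_rng(6)
        fwe = 0
        reps = 200
        for _ in range(reps):
            p = rng.random(3)  # null p-values are uniform
            reject, _ = holm_bonferroni(p, alpha=0.05)
            fwe += reject.any()
        assert fwe / reps < 0.08


class TestMedianSplit:
    def test_constant_outcome(self):
        table = analysis_table(seed=2)
        table["const"] = 1.0
        cells = median_split_summary(table, "igd_c2", "const")
        assert np.allclose(cells["mean"], 1.0)
        assert np.allclose(cells["se"], 0.0)

    def test_constructed_separation(self):
        table = analysis_table(seed=2)
        med = table["igd_c2"].median()
        table["y"] = np.where(table["igd_c2"] <= med, -1.0, 1.0)
        cells = median_split_summary(table, "igd_c2", "y").set_index(["gender", "split"])
        assert cells.loc[("male", "low"), "mean"] == -1.0
        assert cells.loc[("female", "high"), "mean"] == 1.0

    def test_interaction_cohort_shows_crossover(self):
        """With a positive gender x IGD-C2 effect on ln k, high-scoring women
        discount more while the male contrast does not move the same way."""
        table = analysis_table(
            seed=8, effect_gender_memory_on_lnk=4.0, lnk_sd=0.3
        )
        cells = median_split_summary(table, "igd_c2", "ln_k").set_index(
            ["gender", "split"]
        )
        female_diff = cells.loc[("female", "high"), "mean"] - cells.loc[
            ("female", "low"), "mean"
        ]
        male_diff = cells.loc[("male", "high"), "mean"] - cells.loc[
            ("male", "low"), "mean"
        ]
        assert female_diff > 0
        assert female_diff > male_diff
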