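"""CMH, IRLS logistic, association scans and genomic inflation."""

import numpy as np
import pandas as pd
import pytest

from onsetstrat import (ScenarioConfig, association_scan, cmh_allelic_test,
                        fit_logistic, genomic_inflation, simulate_cohort)
from onsetstrat.association import (CHI2_1DF_MEDIAN, LogisticRegressionIRLS,
                                    UntestableError, apply_coding)


class TestCMH:
    def test_single_stratum_equals_crude_or(self):
        res = cmh_allelic_test([[[20, 80], [10, 90]]])
        assert res.or_ == pytest.approx((20 * 90) / (80 * 10), abs=1e-10)
        assert res.test == "cmh"

    def test_replicated_stratum_shrinks_se(self):
        one = cmh_allelic_test([[[20, 80], [10, 90]]])
        two = cmh_allelic_test([[[20, 80], [10, 90]]] * 2)
        assert two.or_ == pytest.approx(one.or_, abs=1e-10)
        assert two.se < one.se

    def test_matches_hand_mh_formula_random_tables(self, rng):
        tables = [rng.integers(5, 60, size=(2, 2)) for _ in range(4)]
        res = cmh_allelic_test(tables)
        num = sum(t[0, 0] * t[1, 1] / t.sum() for t in tables)
        den = sum(t[0, 1] * t[1, 0] / t.sum() for t in tables)
        assert res.or_ == pytest.approx(num / den, rel=1e-10)

    def test_zero_margin_stratum_dropped(self):
        res = cmh_allelic_test([[[20, 80], [10, 90]], [[0, 0], [5, 5]]])
        ref = cmh_allelic_test([[[20, 80], [10, 90]]])
        assert res.or_ == pytest.approx(ref.or_, abs=1e-12)

    def test_all_degenerate_raises(self):
        with pytest.raises(UntestableError):
            cmh_allelic_test([[[0, 0], [5, 5]]])

    def test_null_p_roughly_uniform(self, rng):
        ps = []
        for _ in range(300):
            g = rng.binomial(1, 0.3, size=200)
            y = rng.binomial(1, 0.5, size=200)
            a = int(g[y == 1].sum())
            c = int(g[y == 0].sum())
            t = [[a, int((y == 1).sum()) - a], [c, int((y == 0).sum()) - c]]
            ps.append(cmh_allelic_test([t]).p)
        assert 0.25 < np.mean(np.asarray(ps) < 0.5) < 0.75


class TestLogistic:
    def test_intercept_only_closed_form(self):
        y = (np.arange(100) < 25).astype(float)
        fit = fit_logistic(y, np.empty((100, 0)))
        assert fit.coef_[0] == pytest.approx(np.log(1 / 3), abs=1e-10)

    def test_single_binary_predictor_equals_table_or(self, rng):
        x = rng.binomial(1, 0.4, 500).astype(float)
        y = rng.binomial(1, np.where(x == 1, 0.5, 0.25)).astype(float)
        fit = fit_logistic(y, x)
        a = ((x == 1) & (y == 1)).sum()
        b = ((x == 1) & (y == 0)).sum()
        c = ((x == 0) & (y == 1)).sum()
        d = ((x == 0) & (y == 0)).sum()
        assert fit.coef_[1] == pytest.approx(np.log(a * d / (b * c)), abs=1e-8)

    def test_agrees_with_newton_oracle(self, rng):
        """IRLS estimates and Wald SEs match an independently coded
        Newton-Raphson solver on a 3-column problem."""
        from scipy.special import expit as sigmoid
        n = 400
        X = np.column_stack([np.ones(n), rng.standard_normal(n),
                             rng.binomial(2, 0.3, n)])
        eta = 0.3 * X[:, 1] - 0.5 * X[:, 2] - 0.5
        y = rng.binomial(1, sigmoid(eta)).astype(float)
        beta = np.zeros(3)
        for _ in range(60):
            mu = sigmoid(X @ beta)
            H = X.T @ (X * (mu * (1 - mu))[:, None])
            beta = beta + np.linalg.solve(H, X.T @ (y - mu))
        cov = np.linalg.inv(X.T @ (X * ((sigmoid(X @ beta))
                                        * (1 - sigmoid(X @ beta)))[:, None]))
        fit = LogisticRegressionIRLS(add_intercept=False).fit(X, y)
        assert np.allclose(fit.coef_, beta, atol=1e-8)
        assert np.allclose(fit.se_, np.sqrt(np.diag(cov)), atol=1e-8)

    def test_agrees_with_statsmodels(self, rng):
        import statsmodels.api as sm
        X = np.column_stack([rng.standard_normal(300), rng.binomial(2, 0.2, 300)])
        y = rng.binomial(1, 0.3, 300).astype(float)
        ours = fit_logistic(y, X)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0, method="newton")
        assert np.allclose(ours.coef_, ref.params, atol=1e-7)
        assert np.allclose(ours.se_, ref.bse, atol=1e-6)
        assert ours.loglik_ == pytest.approx(ref.llf, abs=1e-7)

    def test_separation_flagged_not_silent(self):
        x = np.r_[np.zeros(30), np.ones(30)]
        y = x.copy()
        fit = fit_logistic(y, x)
        assert fit.separation_

    def test_rank_deficient_design_rejected(self, rng):
        x = rng.standard_normal(100)
        with pytest.raises(np.linalg.LinAlgError):
            fit_logistic(rng.binomial(1, 0.5, 100), np.column_stack([x, 2 * x]))


class TestScan:
    def test_additive_coding_is_allele_count_regression(self, small_cohort):
        df = small_cohort.data
        y = df["status"].to_numpy(float)
        scan = association_scan(y, df[["g_indel"]], coding="additive")
        direct = fit_logistic(y, df["g_indel"].to_numpy(float))
        assert scan.results["g_indel"].beta == pytest.approx(direct.coef_[1],
                                                             abs=1e-10)

    def test_cmh_used_with_strata(self, small_cohort):
        df = small_cohort.data
        scan = association_scan(df["status"].to_numpy(float),
                                df[["g_indel", "g_snp"]],
                                strata=df["stratum"].to_numpy())
        assert set(scan.table["test"]) == {"cmh"}
        assert scan.results["g_indel"].or_ > 2  # dominant OR 8.1 planted

    def test_monomorphic_variant_flagged(self, small_cohort):
        df = small_cohort.data.copy()
        df["mono"] = 0
        scan = association_scan(df["status"].to_numpy(float), df[["mono"]])
        row = scan.table.iloc[0]
        assert row["flag"] == "monomorphic" and np.isnan(row["beta"])

    def test_male_x_doubling(self):
        y = np.r_[np.ones(50), np.zeros(50)]
        g = np.tile([0, 1], 50).astype(float)
        sex = np.array(["M", "F"] * 50)
        scan = association_scan(y, pd.DataFrame({"x1": g}), x_variants=("x1",),
                                sex=sex, male_x_doubling=True)
        doubled = np.where(sex == "M", 2 * np.minimum(g, 1), g)
        ref = fit_logistic(y, doubled)
        assert scan.results["x1"].beta == pytest.approx(ref.coef_[1], abs=1e-10)

    def test_dominant_coding(self):
        g = np.array([0, 1, 2, 2, 1, 0])
        assert (apply_coding(g, "dominant") == [0, 1, 1, 1, 1, 0]).all()
        assert (apply_coding(g, "recessive") == [0, 0, 1, 1, 0, 0]).all()
        assert (apply_coding(g, "carrier") == apply_coding(g, "dominant")).all()


class TestGenomicInflation:
    def test_definition_and_scale(self, rng):
        assert genomic_inflation([CHI2_1DF_MEDIAN] * 5) == pytest.approx(1.0)
        stats = rng.chisquare(1, 2000)
        assert genomic_inflation(2 * stats) == pytest.approx(
            2 * genomic_inflation(stats), rel=1e-12)

    def test_null_chisquare_lambda_near_one(self, rng):
        stats = rng.chisquare(1, 100_000)
        assert genomic_inflation(stats) == pytest.approx(1.0, abs=0.02)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            genomic_inflation([])
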