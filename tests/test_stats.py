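"""Statistical battery: tests, screens, and the regression models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from supergee.cohort import EDUCATION_LEVELS
from supergee.stats import (
    UndefinedStatisticError,
    chi_square_2x2,
    cohens_d,
    cooks_distances,
    cooks_filter,
    fit_all_models,
    fit_model,
    model_spec,
    or_to_percent_change,
    vif_filter,
    wilcoxon_rank_sum,
)

import statsmodels.api as sm


def make_model_table(n, rng, effects=None, outcome_noise=1.0):
    """Synthetic model-ready table; ``effects`` maps term -> coefficient
    contributions added onto standard-normal outcome columns."""
    effects = effects or {}
    df = pd.DataFrame(
        {
            "age_z": rng.normal(size=n),
            "male": rng.random(n) < 0.4,
            "carrier": rng.random(n) < 0.45,
            "hour_cos_z": rng.normal(size=n),
            "svrt_z": rng.normal(size=n),
            "pal_z": rng.normal(size=n),
            "pal_adj_z": rng.normal(size=n),
            "tint_z": rng.normal(size=n),
            "rt_z": rng.normal(size=n),
            "sr_z": rng.normal(size=n),
            "tr_z": rng.normal(size=n),
            # balanced levels so the collinearity screen never trips here
            "education": rng.choice(EDUCATION_LEVELS, size=n, p=[0.25, 0.25, 0.25, 0.25]),
        }
    )
    eta = np.zeros(n)
    for term, beta in effects.items():
        if ":" in term:
            a, b = term.split(":")
            eta = eta + beta * df[a].astype(float) * df[b].astype(float)
        else:
            eta = eta + beta * df[term].astype(float)
    df["_eta"] = eta + outcome_noise * rng.normal(size=n)
    return df


class TestWilcoxon:
    def test_fully_separated_small_samples_exact_enumeration(self):
        w, p = wilcoxon_rank_sum([1, 2], [3, 4])
        assert w == 0.0
        assert p == pytest.approx(2 / 6)

    def test_identical_samples_p_near_one(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        _, p = wilcoxon_rank_sum(x, x)
        assert p > 0.9

    def test_all_tied_degenerate_data_warns_p_one(self):
        with pytest.warns(UserWarning):
            _, p = wilcoxon_rank_sum([2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0

    def test_exact_and_normal_approximation_agree_untied_n10(self, rng):
        for _ in range(5):
            x, y = rng.normal(size=10), rng.normal(size=10)
            p_exact = sps.mannwhitneyu(x, y, method="exact").pvalue
            p_asymp = sps.mannwhitneyu(
                x, y, method="asymptotic", use_continuity=True
            ).pvalue
            assert abs(p_exact - p_asymp) < 0.01
            assert wilcoxon_rank_sum(x, y)[1] == pytest.approx(p_exact)

    def test_null_calibration(self, rng):
        # 1000 null replicates at n=10/10; exact p-values reject near 5%
        rejections = 0
        for _ in range(1000):
            _, p = wilcoxon_rank_sum(rng.normal(size=10), rng.normal(size=10))
            rejections += p < 0.05
        assert 0.03 <= rejections / 1000 <= 0.07


class TestChiSquare:
    def test_observed_sex_table_is_exactly_zero_with_yates(self):
        chi2, dof, p = chi_square_2x2(np.array([[6, 17], [9, 22]]), yates=True)
        assert chi2 == 0.0
        assert dof == 1
        assert p > 0.99

    def test_uncorrected_pearson_matches_hand_formula(self):
        t = np.array([[6, 17], [9, 22]], dtype=float)
        n = t.sum()
        expected_chi2 = (
            n * (t[0, 0] * t[1, 1] - t[0, 1] * t[1, 0]) ** 2
            / (t[0].sum() * t[1].sum() * t[:, 0].sum() * t[:, 1].sum())
        )
        chi2, _, _ = chi_square_2x2(t, yates=False)
        assert chi2 == pytest.approx(expected_chi2)
        assert chi2 == pytest.approx(0.0571, abs=1e-4)

    def test_perfect_association(self):
        chi2, _, p = chi_square_2x2(np.array([[10, 0], [0, 10]]), yates=False)
        assert chi2 == pytest.approx(20.0)
        assert p < 1e-4

    def test_zero_margin_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            chi_square_2x2(np.array([[0, 0], [5, 7]]))


class TestCohensD:
    def test_identical_groups_zero(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_one_sd_shift_equal_groups_gives_one(self, rng):
        y = rng.normal(size=400)
        x = y + y.std(ddof=1)
        assert cohens_d(x, y) == pytest.approx(1.0, abs=1e-9)

    def test_matches_brute_force_formula(self, rng):
        x, y = rng.normal(2, 3, 37), rng.normal(1, 2, 53)
        pooled = np.sqrt(
            ((len(x) - 1) * np.var(x, ddof=1) + (len(y) - 1) * np.var(y, ddof=1))
            / (len(x) + len(y) - 2)
        )
        assert cohens_d(x, y) == pytest.approx((x.mean() - y.mean()) / pooled)


class TestVif:
    def test_orthogonal_predictors_all_unity_nothing_removed(self, rng):
        raw = rng.normal(size=(100, 4))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        df = pd.DataFrame(q, columns=list("abcd"))
        rep = vif_filter(df, list("abcd"))
        assert rep.removed == []
        assert all(v == pytest.approx(1.0, abs=1e-9) for v in rep.vifs.values())

    def test_duplicated_column_one_of_pair_removed(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=50)})
        df["b"] = df["a"]
        df["c"] = rng.normal(size=50)
        rep = vif_filter(df, ["a", "b", "c"])
        assert len(rep.removed) == 1
        assert rep.removed[0] in {"a", "b"}
        assert "c" in rep.retained

    def test_equicorrelated_trio_matches_closed_form(self, rng):
        # construct exact sample correlation 0.9 via orthonormal basis
        rho = 0.9
        raw = rng.normal(size=(200, 3))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        q /= q.std(axis=0, ddof=1)
        C = np.full((3, 3), rho) + (1 - rho) * np.eye(3)
        X = q @ np.linalg.cholesky(C).T
        df = pd.DataFrame(X, columns=["x1", "x2", "x3"])
        rep = vif_filter(df, ["x1", "x2", "x3"], threshold=np.inf)
        r2 = 2 * rho**2 / (1 + rho)  # R^2 of one on the other two, equicorrelated
        expected = 1.0 / (1.0 - r2)
        for v in rep.vifs.values():
            assert v == pytest.approx(expected, abs=1e-8)

    def test_removal_order_independent_when_vifs_distinct(self, rng):
        base = rng.normal(size=(120, 3))
        df = pd.DataFrame(base, columns=["a", "b", "c"])
        df["d"] = df["a"] * 0.97 + rng.normal(scale=0.1, size=120)
        orders = [["a", "b", "c", "d"], ["d", "c", "b", "a"], ["b", "d", "a", "c"]]
        results = [set(vif_filter(df, order, threshold=5.0).retained) for order in orders]
        assert results[0] == results[1] == results[2]


class TestCooks:
    def test_gross_outlier_only_one_flagged(self, rng):
        x = np.linspace(0, 1, 30)
        y = 2 * x + rng.normal(scale=0.01, size=30)
        x = np.append(x, 10.0)
        y = np.append(y, -50.0)
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        keep, d = cooks_filter(fit, threshold=1.0)
        assert list(np.setdiff1d(np.arange(31), keep)) == [30]
        assert d[30] > 1.0

    def test_matches_leave_one_out_refit_oracle(self, rng):
        n, p = 30, 3
        X = sm.add_constant(rng.normal(size=(n, p - 1)))
        y = X @ np.array([1.0, 2.0, -1.0]) + rng.normal(size=n)
        fit = sm.OLS(y, X).fit()
        d = cooks_distances(fit)
        s2 = fit.mse_resid
        for i in range(n):
            beta_i = sm.OLS(np.delete(y, i), np.delete(X, i, axis=0)).fit().params
            diff = fit.params - beta_i
            d_loo = float(diff @ (X.T @ X) @ diff) / (p * s2)
            assert d[i] == pytest.approx(d_loo, abs=1e-8)

    def test_no_influential_points_leaves_everything(self, rng):
        X = sm.add_constant(rng.normal(size=(60, 2)))
        y = X @ np.array([0.5, 1.0, -0.5]) + rng.normal(size=60)
        keep, _ = cooks_filter(sm.OLS(y, X).fit())
        assert len(keep) == 60


class TestFitModel:
    def test_logistic_parameter_recovery_and_or_identity(self, rng):
        df = make_model_table(2000, rng)
        eta = -1.0 * df["rt_z"]
        df["carrier"] = rng.random(2000) < 1 / (1 + np.exp(-eta))
        res = fit_model(model_spec(1, "rt_z"), df, ci_method="wald")
        row = res.params.loc["rt_z"]
        assert abs(row["coef"] - (-1.0)) < 3 * row["se"]
        np.testing.assert_allclose(res.params["or"], np.exp(res.params["coef"]), rtol=1e-12)
        assert (res.params["ci_low"] <= res.params["ci_high"]).all()

    def test_coefficients_equivariant_under_predictor_scaling(self, rng):
        df = make_model_table(600, rng)
        eta = 0.8 * df["tint_z"] - 0.5 * df["svrt_z"]
        df["carrier"] = rng.random(600) < 1 / (1 + np.exp(-eta))
        res1 = fit_model(model_spec(1, "tint_z"), df, ci_method="wald")
        df2 = df.copy()
        df2["svrt_z"] = df2["svrt_z"] * 2.0
        res2 = fit_model(model_spec(1, "tint_z"), df2, ci_method="wald")
        assert res2.params.loc["svrt_z", "coef"] == pytest.approx(
            res1.params.loc["svrt_z", "coef"] / 2.0, rel=1e-6
        )
        assert res2.params.loc["tint_z", "coef"] == pytest.approx(
            res1.params.loc["tint_z", "coef"], rel=1e-6
        )

    def test_profile_ci_ordered_and_contains_mle(self, rng):
        df = make_model_table(300, rng)
        eta = 0.7 * df["tint_z"]
        df["carrier"] = rng.random(300) < 1 / (1 + np.exp(-eta))
        res = fit_model(model_spec(1, "tint_z"), df, ci_method="profile")
        assert ((res.params["ci_low"] < res.params["coef"])
                & (res.params["coef"] < res.params["ci_high"])).all()

    def test_interaction_power_at_half_sd_effect(self, rng):
        # generative male x TinT interaction of +0.5 SD on the outcome
        hits = 0
        for _ in range(100):
            df = make_model_table(500, rng, effects={"tint_z:male": 0.5})
            df["pal_z"] = df.pop("_eta")
            row = fit_model(model_spec(4, "tint_z"), df, ci_method="wald").params.loc["tint_z:male"]
            hits += (row["coef"] > 0) and (row["p"] < 0.05)
        assert hits >= 80

    def test_linear_type_one_error_calibrated_per_term(self, rng):
        # pure-noise outcome: every term of model 3 rejects at ~5%
        reps = 1000
        counts = None
        for _ in range(reps):
            df = make_model_table(150, rng)
            df["age_z"] = df.pop("_eta")  # independent of all predictors
            p = fit_model(model_spec(3, "tint_z"), df, ci_method="wald").params["p"]
            p = p.drop("const")
            counts = p.lt(0.05).astype(int) if counts is None else counts + p.lt(0.05)
        rates = counts / reps
        assert ((rates >= 0.03) & (rates <= 0.07)).all(), rates.to_dict()

    def test_untripped_screens_equal_unfiltered_fit(self, rng):
        df = make_model_table(250, rng)
        df["age_z"] = 0.4 * df["tint_z"] + rng.normal(size=250)
        spec = model_spec(3, "tint_z")
        res = fit_model(spec, df, ci_method="wald")
        assert res.removed_rows == []
        assert res.removed_predictors == []
        # manual unfiltered fit with the same design
        from supergee.stats import _build_design

        y, X = _build_design(df, spec)
        ref = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
        np.testing.assert_allclose(res.params["coef"], ref.params, rtol=1e-10)

    def test_battery_shapes_and_interactions(self, rng):
        df = make_model_table(200, rng)
        fits = fit_all_models(df, performance="tint_z", ci_method="wald")
        assert set(fits) == {1, 2, 3, 4, 5}
        assert fits[1].spec.kind == "logistic" and fits[3].spec.kind == "linear"
        for m in (4, 5):
            assert "tint_z:male" in fits[m].params.index
        assert fits[5].spec.outcome == "pal_adj_z"


class TestOrInterpretation:
    @pytest.mark.parametrize("orv,expected", [(0.12, 88.0), (1.0, 0.0), (2.5, 150.0)])
    def test_percent_change(self, orv, expected):
        assert or_to_percent_change(orv) == pytest.approx(expected)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            or_to_percent_change(0.0)
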