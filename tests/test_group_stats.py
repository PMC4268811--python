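"""Fixed-effect ANOVA, simple regression, and the ML mixed model."""

import numpy as np
import pandas as pd
import pytest

from retmosaic.group_stats import (
    NonNestedError,
    RankDeficiencyError,
    fit_random_intercept_lmm,
    lrt,
    ols_fit,
    simple_regression,
)


def toy_table(rng=None, n_per_cell=3, noise=0.0):
    rng = rng or np.random.default_rng(0)
    rows = []
    effects = {("A", "F"): 40.0, ("A", "M"): 30.0, ("B", "F"): 44.0, ("B", "M"): 34.0}
    for (strain, sex), mu in effects.items():
        for _ in range(n_per_cell):
            rows.append(
                {"strain": strain, "sex": sex, "resp": mu + noise * rng.normal()}
            )
    return pd.DataFrame(rows)


class TestOls:
    def test_exact_factor_response_gives_zero_residual(self):
        tbl = toy_table(noise=0.0)
        _, aov = ols_fit(tbl, "resp", ["sex", "strain"])
        assert aov.resid_ss == pytest.approx(0.0, abs=1e-18)

    def test_balanced_design_sequential_equals_marginal(self):
        tbl = toy_table(rng=np.random.default_rng(5), noise=1.0)
        _, a1 = ols_fit(tbl, "resp", ["sex", "strain"])
        _, a2 = ols_fit(tbl, "resp", ["strain", "sex"])
        # balance: each term's SS is order-independent
        ss1 = dict(zip(a1.terms, a1.sum_sq))
        ss2 = dict(zip(a2.terms, a2.sum_sq))
        for term in ss1:
            assert ss1[term] == pytest.approx(ss2[term], rel=1e-9)

    def test_sequential_ss_sum_to_total(self):
        tbl = toy_table(rng=np.random.default_rng(2), noise=2.0)
        _, aov = ols_fit(tbl, "resp", ["sex", "strain", "sex:strain"])
        total = ((tbl["resp"] - tbl["resp"].mean()) ** 2).sum()
        assert sum(aov.sum_sq) + aov.resid_ss == pytest.approx(total, rel=1e-12)

    def test_row_permutation_invariance(self):
        tbl = toy_table(rng=np.random.default_rng(3), noise=1.5)
        _, a1 = ols_fit(tbl, "resp", ["sex", "strain"])
        _, a2 = ols_fit(tbl.sample(frac=1.0, random_state=9), "resp", ["sex", "strain"])
        assert a1.f == pytest.approx(a2.f, rel=1e-9)

    def test_rank_deficiency_raises(self):
        tbl = toy_table()
        tbl["sex2"] = tbl["sex"]
        with pytest.raises(RankDeficiencyError):
            ols_fit(tbl, "resp", ["sex", "sex2"])

    def test_order_must_match_terms(self):
        with pytest.raises(ValueError):
            ols_fit(toy_table(), "resp", ["sex"], order=["strain"])


class TestSimpleRegression:
    def test_collinear_points_give_r2_one(self):
        x = np.arange(10.0)
        slope, r2, f, p = simple_regression(2 * x + 1, x)
        assert slope == pytest.approx(2.0)
        assert r2 == pytest.approx(1.0)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            simple_regression([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_f_statistic_identity(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=22)
        y = 0.5 * x + rng.normal(size=22)
        _, r2, f, _ = simple_regression(y, x)
        assert f == pytest.approx(20 * r2 / (1 - r2), rel=1e-12)

    def test_null_mean_r2_matches_beta_expectation(self):
        # under independence R^2 ~ Beta(1/2, (n-2)/2) with mean 1/(n-1)
        rng = np.random.default_rng(123)
        n, sims = 22, 1000
        r2s = [
            simple_regression(rng.normal(size=n), rng.normal(size=n))[1]
            for _ in range(sims)
        ]
        mean_r2 = np.mean(r2s)
        se = np.std(r2s, ddof=1) / np.sqrt(sims)
        assert abs(mean_r2 - 1 / (n - 1)) < 3 * se


def balanced_one_way(k=6, m=8, sd_a=2.0, sd_e=1.0, seed=4):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(k):
        a = rng.normal(0, sd_a)
        for _ in range(m):
            rows.append({"grp": f"g{i}", "y": 10 + a + rng.normal(0, sd_e)})
    return pd.DataFrame(rows)


class TestLmm:
    def test_balanced_one_way_matches_closed_form_ml(self):
        # ML closed forms: sigma_e^2 = SSW/(k(m-1)); sigma_a^2 = (SSB/k - sigma_e^2)/m
        df = balanced_one_way()
        k = df["grp"].nunique()
        m = len(df) // k
        gm = df.groupby("grp")["y"].mean()
        ssw = ((df["y"] - df["grp"].map(gm)) ** 2).sum()
        ssb = m * ((gm - df["y"].mean()) ** 2).sum()
        sig_e = ssw / (k * (m - 1))
        sig_a = (ssb / k - sig_e) / m
        fit = fit_random_intercept_lmm(df, "y", [], ["grp"])
        assert fit.sigma2 == pytest.approx(sig_e, rel=1e-5)
        assert fit.vc["grp"] == pytest.approx(sig_a, rel=1e-4)

    def test_matches_lme4_ml_reference_fit(self):
        # reference values from an lme4 ML fit (REML=FALSE) of
        # value ~ species + sex + (1|strain) + (1|rep_in_strain)
        # on this exact reproducible dataset
        rng = np.random.default_rng(42)
        rows = []
        for i in range(6):
            sp = ["A", "B", "C"][i % 3]
            u = rng.normal(0, 2.0)
            for sex, off in (("F", 2.0), ("M", -2.0)):
                for rep in "ab":
                    rows.append(
                        dict(
                            species=sp, strain=f"s{i}", sex=sex, bio_rep=rep,
                            value=50 + u + off + rng.normal(0, 1.0) + rng.normal(0, 0.8),
                        )
                    )
        df = pd.DataFrame(rows)
        df["rep_in_strain"] = df["strain"] + ":" + df["bio_rep"]
        full = fit_random_intercept_lmm(
            df, "value", ["species", "sex"], ["strain", "rep_in_strain"]
        )
        red = fit_random_intercept_lmm(df, "value", ["species"], ["strain", "rep_in_strain"])
        assert full.loglik == pytest.approx(-32.358226, abs=1e-4)
        assert red.loglik == pytest.approx(-56.519091, abs=1e-4)
        expected = {
            "Intercept": 53.063095,
            "species[T.B]": -1.438082,
            "species[T.C]": 0.451981,
            "sex[T.M]": -4.700786,
        }
        for name, val in expected.items():
            assert full.params[name] == pytest.approx(val, abs=1e-4)
        assert lrt(full, red).x2 == pytest.approx(48.321731, abs=1e-3)

    def test_zero_group_variance_limits_to_ols(self):
        rng = np.random.default_rng(7)
        n = 400
        df = pd.DataFrame(
            {
                "x": rng.normal(size=n),
                "grp": np.repeat([f"g{i}" for i in range(8)], n // 8),
            }
        )
        df["y"] = 1.0 + 2.0 * df["x"] + rng.normal(0, 1.0, size=n)
        fit = fit_random_intercept_lmm(df, "y", ["x"], ["grp"])
        ols = np.polyfit(df["x"], df["y"], 1)
        assert fit.params["x"] == pytest.approx(ols[0], abs=0.02)
        assert fit.vc["grp"] < 0.05

    def test_variance_components_nonnegative_and_loglik_finite(self):
        df = balanced_one_way(seed=9)
        fit = fit_random_intercept_lmm(df, "y", [], ["grp"])
        assert fit.vc["grp"] >= 0
        assert np.isfinite(fit.loglik)
        assert fit.converged

    def test_single_level_grouping_rejected(self):
        df = balanced_one_way()
        df["only"] = "same"
        with pytest.raises(ValueError):
            fit_random_intercept_lmm(df, "y", [], ["only"])


class TestLrt:
    def test_identical_models_give_zero(self):
        df = balanced_one_way()
        fit = fit_random_intercept_lmm(df, "y", [], ["grp"])
        res = lrt(fit, fit)
        assert res.x2 == 0.0 and res.p == 1.0

    def test_three_level_factor_has_df_two(self):
        rng = np.random.default_rng(11)
        df = balanced_one_way(k=6, m=8, seed=11)
        df["species"] = np.tile(["A", "B", "C"], len(df) // 3)
        full = fit_random_intercept_lmm(df, "y", ["species"], ["grp"])
        red = fit_random_intercept_lmm(df, "y", [], ["grp"])
        assert lrt(full, red).df == 2

    def test_non_nested_rejected(self):
        df = balanced_one_way()
        df["x"] = np.arange(len(df), dtype=float)
        df["w"] = df["x"] ** 2
        f1 = fit_random_intercept_lmm(df, "y", ["x"], ["grp"])
        f2 = fit_random_intercept_lmm(df, "y", ["w"], ["grp"])
        with pytest.raises(NonNestedError):
            lrt(f1, f2)
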