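"""Sum-contrast design construction and fixed-effects fits.

The logistic path is cross-checked against a brute-force Newton optimizer
of the exact log-likelihood, and the chance-corrected (guessing-floor)
logistic against a generic optimizer of the same likelihood.
"""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.stats import kstest

import scenecue as s
from scenecue.effects import SeparationError, build_design


def balanced_2x2(n_per_cell=25, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for dur in (50, 500):
        for cond in ("real", "generated"):
            for _ in range(n_per_cell):
                rows.append((cond, dur, rng.normal()))
    return pd.DataFrame(rows, columns=["condition", "duration", "z_anchor"])


class TestBuildDesign:
    def test_documented_level_coding(self):
        df = balanced_2x2()
        d = build_design(df, factors=("condition", "duration"))
        # sorted first level -> +1: 50 before 500, "generated" before "real"
        assert d.factor_codings["duration"] == {50: 1.0, 500: -1.0}
        assert d.factor_codings["condition"] == {"generated": 1.0, "real": -1.0}

    def test_interaction_of_coded_factors_is_pm_one(self):
        df = balanced_2x2()
        d = build_design(df, factors=("condition", "duration"),
                         interactions=(("condition", "duration"),))
        col = d.frame["condition:duration"]
        assert set(col.unique()) == {1.0, -1.0}

    def test_balanced_design_is_orthogonal(self):
        df = balanced_2x2()
        d = build_design(df, factors=("condition", "duration"),
                         interactions=(("condition", "duration"),))
        X = d.frame[["intercept", "condition", "duration", "condition:duration"]].to_numpy()
        gram = X.T @ X
        off = gram - np.diag(np.diag(gram))
        assert np.allclose(off, 0)

    def test_continuous_standardized(self):
        d = build_design(balanced_2x2(), continuous=("z_anchor",))
        col = d.frame["z_anchor"]
        assert abs(col.mean()) < 1e-10 and abs(col.std(ddof=1) - 1) < 1e-10

    def test_three_level_factor_rejected(self):
        df = balanced_2x2()
        df.loc[0, "condition"] = "unsure"
        with pytest.raises(ValueError, match="2 levels"):
            build_design(df, factors=("condition",))

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            build_design(balanced_2x2(), factors=("nonexistent",))


def newton_logistic_oracle(X, y, tol=1e-12, max_iter=200):
    """Independent brute-force Newton optimizer of the exact logistic
    log-likelihood (no IRLS framing, no statsmodels)."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = 1 / (1 + np.exp(-eta))
        grad = X.T @ (y - p)
        hess = -(X.T * (p * (1 - p))) @ X
        step = np.linalg.solve(hess, grad)
        beta = beta - step
        if np.max(np.abs(step)) < tol:
            break
    return beta


class TestLogisticFit:
    def test_closed_form_2x2_log_odds(self):
        # 40/10 successes in the +1 cell, 10/40 in the -1 cell:
        # slope = (logit(0.8) - logit(0.2)) / 2 = log(16) / 2
        rows = []
        for grp, n1, n0 in (("a", 40, 10), ("b", 10, 40)):
            rows += [(grp, 1)] * n1 + [(grp, 0)] * n0
        df = pd.DataFrame(rows, columns=["group", "y"])
        fit = s.EffectsModel.from_dataframe(df, "y", factors=("group",),
                                            family="logistic").fit()
        assert fit.params["group"] == pytest.approx(np.log(16) / 2, abs=1e-6)
        assert fit.params["intercept"] == pytest.approx(0.0, abs=1e-6)

    def test_matches_newton_oracle(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(80), rng.normal(size=(80, 2))])
        y = (rng.random(80) < 1 / (1 + np.exp(-(0.3 + X[:, 1] - 0.5 * X[:, 2])))).astype(float)
        df = pd.DataFrame({"y": y, "x1": X[:, 1], "x2": X[:, 2]})
        fit = s.EffectsModel.from_dataframe(df, "y", continuous=("x1", "x2"),
                                            family="logistic").fit()
        # oracle works on the same standardized design
        beta_oracle = newton_logistic_oracle(fit.design.matrix, y)
        assert np.max(np.abs(fit.params.to_numpy() - beta_oracle)) < 1e-8

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(2)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            df = pd.DataFrame({"y": rng.integers(0, 2, 150),
                               "x": rng.normal(size=150)})
            fit = s.EffectsModel.from_dataframe(df, "y", continuous=("x",),
                                                family="logistic").fit()
            rejections += abs(fit.statistic["x"]) > 1.96
        # binomial 99.5% interval around 0.05
        assert rejections < n_rep * 0.05 + 2.81 * np.sqrt(n_rep * 0.05 * 0.95)

    def test_perfect_separation_raises(self):
        x = np.linspace(-2, 2, 40)
        df = pd.DataFrame({"y": (x > 0).astype(int), "x": x})
        with pytest.raises(SeparationError):
            s.EffectsModel.from_dataframe(df, "y", continuous=("x",),
                                          family="logistic").fit()

    def test_rank_deficient_design_rejected(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"y": rng.integers(0, 2, 50), "x": rng.normal(size=50)})
        df["x2"] = df["x"]
        design = build_design(df, continuous=("x",))
        design.frame["dup"] = design.frame["x"]
        with pytest.raises(ValueError, match="rank deficient"):
            s.EffectsModel(df["y"].to_numpy(), design, family="logistic")


class TestGuessRateLogistic:
    def test_matches_generic_optimizer(self):
        rng = np.random.default_rng(4)
        n = 400
        x = rng.normal(size=n)
        eta = 0.4 + 0.8 * x
        p = 0.2 + 0.8 / (1 + np.exp(-eta))
        y = (rng.random(n) < p).astype(float)
        df = pd.DataFrame({"y": y, "x": x})
        fit = s.EffectsModel.from_dataframe(df, "y", continuous=("x",),
                                            family="logistic", guess_rate=0.2).fit()
        X = fit.design.matrix

        def negll(beta):
            pr = 0.2 + 0.8 / (1 + np.exp(-(X @ beta)))
            pr = np.clip(pr, 1e-12, 1 - 1e-12)
            return -np.sum(y * np.log(pr) + (1 - y) * np.log(1 - pr))

        opt = minimize(negll, np.zeros(2), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        assert np.max(np.abs(fit.params.to_numpy() - opt.x)) < 1e-5

    def test_zero_guess_rate_equals_plain_logistic(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"y": rng.integers(0, 2, 120), "x": rng.normal(size=120)})
        plain = s.EffectsModel.from_dataframe(df, "y", continuous=("x",),
                                              family="logistic").fit()
        corrected = s.EffectsModel.from_dataframe(df, "y", continuous=("x",),
                                                  family="logistic", guess_rate=0.0).fit()
        assert np.allclose(plain.params, corrected.params, atol=1e-7)


class TestLinearFit:
    def test_exact_linear_fit_flagged_degenerate(self):
        df = balanced_2x2()
        df["y"] = 2.0 + 0.5 * df["z_anchor"]
        fit = s.EffectsModel.from_dataframe(df, "y", continuous=("z_anchor",),
                                            family="linear").fit()
        assert fit.degenerate
        assert np.allclose(fit.params["z_anchor"],
                           0.5 * df["z_anchor"].std(ddof=1), atol=1e-8)

    def test_sum_coded_main_effect_is_half_cell_mean_difference(self):
        df = balanced_2x2(n_per_cell=30, seed=6)
        rng = np.random.default_rng(7)
        df["y"] = np.where(df["condition"] == "generated", 1.0, 2.0) + rng.normal(0, 0.3, len(df))
        fit = s.EffectsModel.from_dataframe(df, "y", factors=("condition",),
                                            family="linear").fit()
        cell_means = df.groupby("condition")["y"].mean()
        expected = (cell_means["generated"] - cell_means["real"]) / 2
        assert fit.params["condition"] == pytest.approx(expected, abs=1e-10)

    def test_permutation_null_pvalues_uniform(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=60)
        y = rng.normal(size=60)
        pvals = []
        for _ in range(500):
            yp = rng.permutation(y)
            df = pd.DataFrame({"y": yp, "x": x})
            fit = s.EffectsModel.from_dataframe(df, "y", continuous=("x",),
                                                family="linear").fit()
            pvals.append(fit.pvalues["x"])
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestLinearTrend:
    @pytest.fixture
    def interaction_fit(self):
        rng = np.random.default_rng(99)  # distinct stream from the covariates
        df = balanced_2x2(n_per_cell=200, seed=9)
        code = np.where(df["condition"] == "generated", 1.0, -1.0)
        z = s.z_transform(df["z_anchor"].to_numpy())
        # planted per-condition slopes -0.15 (generated) and +0.08 (real)
        b_cont, b_int = (-0.15 + 0.08) / 2, (-0.15 - 0.08) / 2
        df["y"] = 1.0 + b_cont * z + b_int * code * z + rng.normal(0, 0.2, len(df))
        return s.EffectsModel.from_dataframe(
            df, "y", factors=("condition",), continuous=("z_anchor",),
            interactions=(("condition", "z_anchor"),), family="linear").fit()

    def test_recovers_planted_per_condition_slopes(self, interaction_fit):
        trends = interaction_fit.linear_trend("z_anchor", "condition").set_index("level")
        g = trends.loc["generated"]
        r = trends.loc["real"]
        assert g["ci_lower"] <= -0.15 <= g["ci_upper"]
        assert r["ci_lower"] <= 0.08 <= r["ci_upper"]

    def test_slope_average_equals_main_effect_exactly(self, interaction_fit):
        trends = interaction_fit.linear_trend("z_anchor", "condition")
        assert trends["slope"].mean() == pytest.approx(
            interaction_fit.params["z_anchor"], abs=1e-12)

    def test_zero_interaction_gives_equal_slopes(self):
        df = balanced_2x2(n_per_cell=50, seed=10)
        rng = np.random.default_rng(110)
        df["y"] = 0.3 * df["z_anchor"] + rng.normal(0, 0.1, len(df))
        fit = s.EffectsModel.from_dataframe(
            df, "y", factors=("condition",), continuous=("z_anchor",),
            interactions=(("condition", "z_anchor"),), family="linear").fit()
        trends = fit.linear_trend("z_anchor", "condition")
        assert abs(trends["slope"].iloc[0] - trends["slope"].iloc[1]) == pytest.approx(
            2 * abs(fit.params["condition:z_anchor"]), abs=1e-12)

    def test_missing_interaction_rejected(self):
        df = balanced_2x2()
        rng = np.random.default_rng(11)
        df["y"] = rng.normal(size=len(df))
        fit = s.EffectsModel.from_dataframe(df, "y", factors=("condition",),
                                            continuous=("z_anchor",),
                                            family="linear").fit()
        with pytest.raises(ValueError, match="interaction"):
            fit.linear_trend("z_anchor", "condition")


class TestResultsSurface:
    def test_wald_ci_and_summary(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame({"y": rng.integers(0, 2, 200), "x": rng.normal(size=200)})
        fit = s.EffectsModel.from_dataframe(df, "y", continuous=("x",),
                                            family="logistic").fit()
        ci = fit.conf_int()
        half = 1.959964 * fit.bse
        assert np.allclose(ci["upper"] - fit.params, half, atol=1e-9)
        text = fit.summary()
        assert "logistic" in text and "intercept" in text

    def test_participant_indicators_absorb_intercepts(self):
        rng = np.random.default_rng(13)
        n_p, n_t = 10, 40
        intercepts = rng.normal(0, 1.0, n_p)
        x = rng.normal(size=n_p * n_t)
        part = np.repeat(np.arange(n_p), n_t)
        y = 0.5 * x + intercepts[part] + rng.normal(0, 0.5, n_p * n_t)
        df = pd.DataFrame({"y": y, "x": x, "participant": part})
        with_ind = s.EffectsModel.from_dataframe(
            df, "y", continuous=("x",), family="linear",
            include_participant=True).fit()
        without = s.EffectsModel.from_dataframe(
            df, "y", continuous=("x",), family="linear").fit()
        assert with_ind.bse["x"] < without.bse["x"]
        sd = df["x"].std(ddof=1)
        ci = with_ind.conf_int().loc["x"]
        assert ci["lower"] <= 0.5 * sd <= ci["upper"]
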