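"""Regression core: OLS, NB GLM, LRT, deviance decomposition, VIF,
backward AIC and PCA reduction."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from seasonmix import (
    backward_aic,
    deviance_explained,
    explained_deviance,
    fit_linear,
    fit_nb_glm,
    lrt_importance,
    pca_reduce,
    r2_decomposition,
    vif,
)
from seasonmix.exceptions import (
    DegenerateInputError,
    InputError,
    SingularDesignError,
)


def _xdf(arr, names):
    return pd.DataFrame(np.asarray(arr, float).T, columns=names)


class TestLinear:
    def test_exact_line_recovered(self):
        x = np.arange(6.0)
        fit = fit_linear(2 * x + 1, _xdf([x], ["x"]))
        assert fit.params["const"] == pytest.approx(1.0)
        assert fit.params["x"] == pytest.approx(2.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self, rng):
        n, p = 5, 2
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        fit = fit_linear(y, _xdf(X.T, ["a", "b"]))
        Xc = np.column_stack([np.ones(n), X])
        beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ y)
        np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-10)

    def test_rank_deficient_design_rejected(self, rng):
        x = rng.normal(size=20)
        with pytest.raises(SingularDesignError):
            fit_linear(rng.normal(size=20), _xdf([x, 2 * x], ["a", "b"]))

    def test_pure_noise_gives_small_r2(self, rng):
        y = rng.normal(size=300)
        X = _xdf([rng.normal(size=300)], ["x"])
        assert fit_linear(y, X).r_squared < 0.05


class TestLRT:
    def test_zero_effect_orthogonal_column_gives_zero_statistic(self, rng):
        # project z out of span(1, x, y): its OLS coefficient is exactly
        # zero, so removing it leaves the likelihood unchanged
        n = 30
        x = rng.normal(size=n)
        y = 2 * x + rng.normal(size=n)
        basis = np.linalg.qr(np.column_stack([np.ones(n), x, y]))[0]
        z = rng.normal(size=n)
        z = z - basis @ (basis.T @ z)
        res = lrt_importance(y, _xdf([x, z], ["x", "z"]), {"z": ["z"]})
        assert res.loc["z", "statistic"] == pytest.approx(0.0, abs=1e-8)
        assert res.loc["z", "pvalue"] == pytest.approx(1.0, abs=1e-6)

    def test_statistic_is_twice_loglik_gap(self, rng):
        X = rng.normal(size=(60, 3))
        y = X[:, 0] + rng.normal(size=60)
        xdf = _xdf(X.T, ["a", "b", "c"])
        res = lrt_importance(y, xdf, {"bc": ["b", "c"]})
        full = sm.OLS(y, sm.add_constant(X)).fit().llf
        red = sm.OLS(y, sm.add_constant(X[:, [0]])).fit().llf
        assert res.loc["bc", "statistic"] == pytest.approx(2 * (full - red), abs=1e-8)
        assert res.loc["bc", "df"] == 2

    def test_null_pvalues_approximately_uniform(self):
        rng = np.random.default_rng(77)
        pvals = []
        for _ in range(300):
            X = rng.normal(size=(40, 2))
            y = X[:, 0] * 0.5 + rng.normal(size=40)  # second column is null
            res = lrt_importance(y, _xdf(X.T, ["a", "b"]), {"b": ["b"]})
            pvals.append(res.loc["b", "pvalue"])
        from scipy import stats

        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_empty_group_rejected(self, rng):
        X = _xdf([rng.normal(size=30)], ["x"])
        with pytest.raises(InputError):
            lrt_importance(rng.normal(size=30), X, {"none": []})


class TestR2Decomposition:
    def test_orthogonal_predictors_decompose_additively(self):
        n = 32
        t = np.arange(n)
        x1 = np.cos(2 * np.pi * t / n)
        x2 = np.sin(2 * np.pi * t / n)  # orthogonal to x1 and to constants
        y = 2 * x1 - x2 + np.random.default_rng(1).normal(size=n)
        r2, dr2 = r2_decomposition(y, _xdf([x1, x2], ["x1", "x2"]))
        assert dr2.sum() == pytest.approx(r2, abs=1e-10)
        assert (dr2 >= 0).all()

    def test_null_group_contribution_vanishes_at_large_n(self, rng):
        n = 4000
        X = rng.normal(size=(n, 2))
        y = X[:, 0] + rng.normal(size=n)
        _, dr2 = r2_decomposition(y, _xdf(X.T, ["sig", "null"]))
        assert dr2["null"] < 0.005
        assert dr2["sig"] > 0.3


class TestNbGlm:
    def test_intercept_only_mle_is_weighted_mean(self, rng):
        y = rng.poisson(6.0, size=200)
        w = rng.uniform(0.2, 1.0, size=200)
        fit = fit_nb_glm(y, pd.DataFrame({"const": np.ones(200)}), weights=w)
        assert np.exp(fit.params["const"]) == pytest.approx(
            np.average(y, weights=w), rel=1e-6
        )

    def test_poisson_data_matches_poisson_glm_oracle(self, rng):
        n = 2000
        x = rng.normal(size=n)
        y = rng.poisson(np.exp(1.0 + 0.5 * x))
        xdf = _xdf([x], ["x"])
        fit = fit_nb_glm(y, xdf)
        oracle = sm.GLM(
            y, sm.add_constant(x), family=sm.families.Poisson()
        ).fit()
        np.testing.assert_allclose(
            fit.params.to_numpy(), oracle.params, atol=1e-3
        )
        assert fit.theta > 100
        assert fit.poisson_like

    def test_nb_parameters_recovered(self, rng):
        n = 2000
        x = rng.normal(size=n)
        mu = np.exp(1.2 - 0.6 * x)
        theta = 2.0
        y = rng.poisson(rng.gamma(theta, mu / theta))
        fit = fit_nb_glm(y, _xdf([x], ["x"]))
        for name, true in [("const", 1.2), ("x", -0.6)]:
            assert abs(fit.params[name] - true) < 3 * fit.bse[name]
        assert abs(fit.theta - theta) / theta < 0.30

    def test_profile_maximality_of_theta(self, rng):
        from seasonmix.regression import _nb_loglik

        y = rng.poisson(rng.gamma(3.0, 5.0 / 3.0, size=500))
        fit = fit_nb_glm(y, pd.DataFrame({"const": np.ones(500)}))
        mu = np.full(500, np.exp(fit.params["const"]))
        best = _nb_loglik(y, mu, fit.theta)
        for theta in [0.5, 1.0, 2.0, 5.0, 10.0, 100.0]:
            assert best >= _nb_loglik(y, mu, theta) - 1e-8

    def test_all_zero_counts_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_nb_glm(np.zeros(10), pd.DataFrame({"const": np.ones(10)}))


class TestDevianceExplained:
    @pytest.mark.parametrize(
        "null,resid,expected", [(200.0, 100.0, 50.0), (200.0, 200.0, 0.0),
                                (200.0, 0.0, 100.0)]
    )
    def test_formula_hand_cases(self, null, resid, expected):
        assert explained_deviance(null, resid) == expected

    def test_zero_null_deviance_rejected(self):
        with pytest.raises(DegenerateInputError):
            explained_deviance(0.0, 0.0)

    def test_gaussian_d_equals_100_r2_and_deltas_nonnegative(self, rng):
        X = rng.normal(size=(100, 3))
        y = X @ [1.0, 0.5, 0.0] + rng.normal(size=100)
        fit = fit_linear(y, _xdf(X.T, ["a", "b", "c"]))
        d, delta = deviance_explained(fit)
        assert d == pytest.approx(100 * fit.r_squared)
        assert (delta >= 0).all() and 0 <= d <= 100

    def test_d_invariant_to_affine_rescaling_of_predictors(self, rng):
        X = rng.normal(size=(80, 2))
        y = rng.poisson(np.exp(1.0 + 0.4 * X[:, 0] - 0.3 * X[:, 1]))
        d1, _ = deviance_explained(fit_nb_glm(y, _xdf(X.T, ["a", "b"])))
        Xr = X * [10.0, 0.2] + [5.0, -3.0]
        d2, _ = deviance_explained(fit_nb_glm(y, _xdf(Xr.T, ["a", "b"])))
        assert d1 == pytest.approx(d2, abs=1e-6)


class TestVif:
    def test_orthogonal_predictors_have_unit_vif(self):
        n = 16
        t = np.arange(n)
        X = _xdf(
            [np.cos(2 * np.pi * t / n), np.sin(2 * np.pi * t / n)], ["c", "s"]
        )
        np.testing.assert_allclose(vif(X), 1.0, atol=1e-10)

    def test_duplicated_column_reports_infinite_vif(self, rng):
        x = rng.normal(size=30)
        v = vif(_xdf([x, x, rng.normal(size=30)], ["a", "b", "c"]))
        assert np.isinf(v["a"]) and np.isinf(v["b"])

    def test_known_correlation_gives_closed_form_vif(self):
        # build two columns with empirical correlation exactly 0.9
        n = 50
        u1 = np.zeros(n)
        u1[: n // 2] = 1.0
        u1 = (u1 - u1.mean()) / np.linalg.norm(u1 - u1.mean())
        u2 = np.zeros(n)
        u2[::2] = 1.0
        u2 = u2 - u2.mean() - u1 * (u1 @ (u2 - u2.mean()))
        u2 /= np.linalg.norm(u2)
        x2 = 0.9 * u1 + np.sqrt(1 - 0.81) * u2
        v = vif(_xdf([u1, x2], ["a", "b"]))
        assert v["a"] == pytest.approx(1 / (1 - 0.81), rel=1e-9)


class TestBackwardAic:
    def test_noise_dropped_signal_kept(self, rng):
        n = 500
        X = rng.normal(size=(n, 2))
        y = 2.0 * X[:, 0] + rng.normal(size=n)
        fit, path = backward_aic(y, _xdf(X.T, ["signal", "noise"]))
        assert "signal" in fit.params.index
        assert "noise" not in fit.params.index
        assert path["aic"].is_monotonic_decreasing

    def test_pure_noise_response_reduces_to_intercept(self):
        # each null predictor survives with probability ~0.157, so the
        # intercept-only model is selected in ~0.843^3 ~ 60% of runs
        rng = np.random.default_rng(4)
        hits = 0
        for _ in range(20):
            X = rng.normal(size=(500, 3))
            y = rng.normal(size=500)
            fit, _ = backward_aic(y, _xdf(X.T, ["a", "b", "c"]))
            if list(fit.params.index) == ["const"]:
                hits += 1
        assert hits >= 7

    def test_all_strong_effects_retained(self, rng):
        X = rng.normal(size=(500, 3))
        y = X @ [1.0, -1.0, 1.0] + rng.normal(size=500)
        fit, path = backward_aic(y, _xdf(X.T, ["a", "b", "c"]))
        assert set(fit.params.index) == {"const", "a", "b", "c"}
        assert len(path) == 1

    def test_nb_family_selection(self, rng):
        n = 400
        X = rng.normal(size=(n, 2))
        y = rng.poisson(np.exp(1.0 + 0.8 * X[:, 0]))
        fit, _ = backward_aic(y, _xdf(X.T, ["sig", "noise"]), family="nb")
        assert "sig" in fit.params.index


class TestPcaReduce:
    def test_perfectly_correlated_pair_explains_everything(self, rng):
        x = rng.normal(size=40)
        block = pd.DataFrame({"a": x, "b": 2 * x + 1})
        res = pca_reduce(block, anchor="a")
        assert res.var_fraction == pytest.approx(1.0)
        assert np.linalg.norm(res.loadings) == pytest.approx(1.0)

    def test_anchor_loading_always_positive(self, rng):
        block = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        for anchor in "abcd":
            assert pca_reduce(block, anchor=anchor).loadings[anchor] > 0

    def test_independent_variables_spread_variance(self, rng):
        p = 4
        block = pd.DataFrame(
            rng.normal(size=(3000, p)), columns=[f"v{i}" for i in range(p)]
        )
        res = pca_reduce(block, anchor="v0")
        assert abs(res.var_fraction - 1 / p) < 0.05

    def test_constant_variable_rejected(self, rng):
        block = pd.DataFrame({"a": rng.normal(size=10), "b": np.ones(10)})
        with pytest.raises(DegenerateInputError):
            pca_reduce(block, anchor="a")
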