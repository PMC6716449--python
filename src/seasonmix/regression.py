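"""Single-model statistics shared by every pipeline stage.

Gaussian linear models (ordinary least squares), negative-binomial GLMs
with maximum-likelihood dispersion profiling, likelihood-ratio importance
tests for covariate groups, R-squared and explained-deviance
decompositions, variance inflation factors, backward-AIC model selection,
and PCA reduction of environmental variable blocks.

Conventions
-----------
* The NB model is parameterized by mean ``mu`` (log link) and dispersion
  ``theta`` with variance ``mu + mu**2/theta``; ``theta`` is profiled by
  maximum likelihood within [1e-3, 1e6] and a fit sitting at the upper
  bound is flagged ``poisson_like``.
* Explained deviance ``D = 100 * (null - residual) / null`` deviance, in
  percent.  ``Delta D`` (and ``Delta R2``) for a covariate group is the
  drop full-minus-reduced, refitting the reduced model; for NB reduced
  fits the dispersion is held at the full model's value so the decrease
  is non-negative by nesting.
* AIC here is ``-2 loglik + 2k`` with ``k`` counting every estimated
  parameter including the Gaussian scale or NB dispersion.
* Coefficient p-values are Wald tests: t for Gaussian, z for NB.  The
  group likelihood-ratio test is exposed separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats

from .design import CovariateMatrix
from .exceptions import (
    ConvergenceError,
    DegenerateInputError,
    InputError,
    SingularDesignError,
)

THETA_BOUNDS = (1e-3, 1e6)


# ---------------------------------------------------------------------------
# containers


@dataclass
class RegressionResult:
    """A fitted Gaussian or negative-binomial regression."""

    family: str                      # "gaussian" | "nb"
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    loglik: float
    aic: float
    n_params: int
    nobs: float
    null_deviance: float
    resid_deviance: float
    theta: float | None = None
    poisson_like: bool = False
    r_squared: float | None = None
    _y: np.ndarray = field(default=None, repr=False)
    _X: pd.DataFrame = field(default=None, repr=False)
    _weights: np.ndarray = field(default=None, repr=False)

    @property
    def D(self) -> float:
        """Percentage of explained deviance."""
        return explained_deviance(self.null_deviance, self.resid_deviance)


@dataclass
class PCAResult:
    """First principal component of a standardized variable block."""

    scores: pd.Series
    loadings: pd.Series
    var_fraction: float
    anchor: str


def explained_deviance(null_deviance: float, resid_deviance: float) -> float:
    """D = 100 * (null deviance - residual deviance) / null deviance."""
    if null_deviance <= 0:
        raise DegenerateInputError("null deviance is zero; D is undefined")
    return 100.0 * (null_deviance - resid_deviance) / null_deviance


# ---------------------------------------------------------------------------
# design-matrix plumbing


def _as_model_matrix(X, n: int) -> pd.DataFrame:
    """Coerce X (CovariateMatrix / DataFrame / ndarray) to a model matrix
    with a leading 'const' column."""
    if isinstance(X, CovariateMatrix):
        out = X.design_matrix()
    elif isinstance(X, pd.DataFrame):
        out = X.copy()
        if "const" not in out.columns:
            out.insert(0, "const", 1.0)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        out = pd.DataFrame(arr, columns=[f"x{i}" for i in range(arr.shape[1])])
        out.insert(0, "const", 1.0)
    if len(out) != n:
        raise InputError(f"X has {len(out)} rows but y has {n}")
    return out.astype(float)


def _check_rank(X: pd.DataFrame):
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise SingularDesignError("design matrix is rank deficient")


# ---------------------------------------------------------------------------
# gaussian


def fit_linear(y, X) -> RegressionResult:
    """Ordinary least squares with an intercept.

    Deviances are residual sums of squares, so D equals 100 * R2 for the
    model against the intercept-only null.
    """
    y = np.asarray(y, dtype=float)
    xdf = _as_model_matrix(X, len(y))
    if len(y) <= xdf.shape[1]:
        raise InputError("need more observations than parameters")
    _check_rank(xdf)
    res = sm.OLS(y, xdf).fit()
    k = xdf.shape[1] + 1  # + error variance
    rss = float(np.sum(res.resid**2))
    tss = float(np.sum((y - y.mean()) ** 2))
    return RegressionResult(
        family="gaussian",
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        loglik=float(res.llf),
        aic=-2.0 * float(res.llf) + 2.0 * k,
        n_params=k,
        nobs=float(len(y)),
        null_deviance=tss,
        resid_deviance=rss,
        r_squared=float(res.rsquared),
        _y=y,
        _X=xdf,
    )


# ---------------------------------------------------------------------------
# negative binomial


def _nb_loglik(y, mu, theta, weights=None) -> float:
    """Weighted NB log-likelihood at mean mu, dispersion theta."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-300)
    ll = (
        special.gammaln(y + theta)
        - special.gammaln(theta)
        - special.gammaln(y + 1.0)
        + theta * np.log(theta / (theta + mu))
        + special.xlogy(y, mu) - special.xlogy(y, theta + mu)
    )
    if weights is None:
        return float(ll.sum())
    return float(np.dot(np.asarray(weights, dtype=float), ll))


def _profile_theta(y, mu, weights=None, bounds=THETA_BOUNDS) -> float:
    """Maximize the NB log-likelihood over theta at fixed mu."""
    res = optimize.minimize_scalar(
        lambda lt: -_nb_loglik(y, mu, np.exp(lt), weights),
        bounds=(np.log(bounds[0]), np.log(bounds[1])),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(np.exp(res.x))


def _nb_deviance(y, mu, theta, weights=None) -> float:
    """NB deviance at fixed theta: 2 * sum w [y log(y/mu) -
    (y+theta) log((y+theta)/(mu+theta))]."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-300)
    unit = 2.0 * (
        special.xlogy(y, y) - special.xlogy(y, mu)
        - (y + theta) * (np.log(y + theta) - np.log(mu + theta))
    )
    if weights is None:
        return float(unit.sum())
    return float(np.dot(np.asarray(weights, dtype=float), unit))


def fit_nb_glm(y, X, weights=None, theta: float | None = None,
               max_iter: int = 100, tol: float = 1e-10,
               theta_bounds=THETA_BOUNDS, start_params=None) -> RegressionResult:
    """Log-link negative-binomial regression, optionally observation-weighted.

    Coefficients come from iteratively reweighted least squares at the
    current dispersion; the dispersion is profiled by maximum likelihood;
    the two are alternated to joint convergence.  Passing ``theta`` fixes
    the dispersion (used for nested refits inside deviance decompositions,
    and by the EM mixture driver).

    ``weights`` are likelihood weights (each observation's log-likelihood
    contribution is multiplied by its weight); fractional values such as
    EM responsibilities are fine.
    """
    y = np.asarray(y, dtype=float)
    xdf = _as_model_matrix(X, len(y))
    _check_rank(xdf)
    if (y < 0).any():
        raise InputError("counts must be non-negative")
    w = None if weights is None else np.asarray(weights, dtype=float)
    if w is not None and (w < 0).any():
        raise InputError("weights must be non-negative")
    wsum = float(len(y)) if w is None else float(w.sum())
    wy = float(y.sum()) if w is None else float(np.dot(w, y))
    if wy <= 0:
        raise DegenerateInputError("all (weighted) counts are zero")

    fixed_theta = theta is not None
    if theta is None:
        ybar = wy / wsum
        yvar = (
            float(np.average((y - ybar) ** 2, weights=w))
            if wsum > 0
            else 0.0
        )
        theta = (
            np.clip(ybar**2 / max(yvar - ybar, 1e-8), *theta_bounds)
            if yvar > ybar
            else theta_bounds[1]
        )

    params = start_params
    ll_prev = -np.inf
    converged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(max_iter):
            model = sm.GLM(
                y, xdf,
                family=sm.families.NegativeBinomial(alpha=1.0 / theta),
                freq_weights=w,
            )
            res = model.fit(start_params=params, maxiter=200)
            params = np.asarray(res.params)
            mu = np.asarray(res.mu)
            if not fixed_theta:
                theta = _profile_theta(y, mu, w, theta_bounds)
            ll = _nb_loglik(y, mu, theta, w)
            if np.abs(ll - ll_prev) < tol * (np.abs(ll_prev) + 1.0):
                converged = True
                break
            ll_prev = ll
            if fixed_theta:
                # beta is the only free block; one more pass confirms
                continue
    if not converged and not fixed_theta:
        raise ConvergenceError(
            "NB fit did not converge",
            {"loglik": ll, "theta": theta, "iterations": max_iter},
        )

    mu0 = wy / wsum  # intercept-only MLE at any fixed theta
    null_dev = _nb_deviance(y, np.full_like(y, mu0), theta, w)
    resid_dev = _nb_deviance(y, mu, theta, w)
    k = xdf.shape[1] + (0 if fixed_theta else 1)
    coef = pd.Series(params, index=xdf.columns)
    bse = pd.Series(np.asarray(res.bse), index=xdf.columns)
    zval = coef / bse
    return RegressionResult(
        family="nb",
        params=coef,
        bse=bse,
        pvalues=pd.Series(2.0 * stats.norm.sf(np.abs(zval)), index=xdf.columns),
        loglik=ll,
        aic=-2.0 * ll + 2.0 * k,
        n_params=k,
        nobs=wsum,
        null_deviance=null_dev,
        resid_deviance=resid_dev,
        theta=float(theta),
        poisson_like=bool(theta >= 0.5 * theta_bounds[1]),
        _y=y,
        _X=xdf,
        _weights=w,
    )


# ---------------------------------------------------------------------------
# decompositions and tests


def _refit_without(fit: RegressionResult, drop_cols) -> RegressionResult:
    xred = fit._X.drop(columns=list(drop_cols))
    if fit.family == "gaussian":
        return fit_linear(fit._y, xred)
    return fit_nb_glm(fit._y, xred, weights=fit._weights, theta=fit.theta)


def _default_groups(fit: RegressionResult) -> dict[str, list[str]]:
    return {c: [c] for c in fit._X.columns if c != "const"}


def deviance_explained(fit: RegressionResult, groups=None):
    """D of a fitted model and the per-group drops Delta D.

    ``groups`` maps group name -> list of column names; default is one
    group per non-intercept column.  Reduced models are refit without the
    group's columns (NB refits hold theta at the full fit's value).
    Returns ``(D, Series of Delta D)``.
    """
    groups = groups or _default_groups(fit)
    d_full = fit.D
    out = {}
    for name, cols in groups.items():
        if not cols:
            raise InputError(f"group {name!r} is empty")
        missing = [c for c in cols if c not in fit._X.columns]
        if missing:
            raise InputError(f"group {name!r} names unknown columns {missing}")
        reduced = _refit_without(fit, cols)
        d_red = explained_deviance(fit.null_deviance, reduced.resid_deviance)
        out[name] = max(d_full - d_red, 0.0)
    return d_full, pd.Series(out, name="delta_D")


def r2_decomposition(y, X, groups=None):
    """R2 of the full Gaussian fit and semi-partial Delta R2 per group.

    Delta R2(group) = R2(full) - R2(full minus group), never negative.
    Returns ``(R2, Series of Delta R2)``.
    """
    full = fit_linear(y, X)
    groups = groups or _default_groups(full)
    out = {}
    for name, cols in groups.items():
        if not cols:
            raise InputError(f"group {name!r} is empty")
        reduced = _refit_without(full, cols)
        out[name] = max(full.r_squared - reduced.r_squared, 0.0)
    return full.r_squared, pd.Series(out, name="delta_R2")


def lrt_importance(y, X, groups=None, family: str = "gaussian") -> pd.DataFrame:
    """Group likelihood-ratio tests against the full model.

    For each covariate group the full model is compared with the model
    lacking that group; the statistic 2*(loglik_full - loglik_reduced) is
    referred to chi-squared with df = group size.
    """
    full = fit_linear(y, X) if family == "gaussian" else fit_nb_glm(y, X)
    groups = groups or _default_groups(full)
    rows = []
    for name, cols in groups.items():
        if not cols:
            raise InputError(f"group {name!r} is empty")
        reduced = _refit_without(full, cols)
        if family == "nb":
            # re-profile theta in the reduced model for a genuine LRT
            reduced = fit_nb_glm(full._y, full._X.drop(columns=cols))
        stat = max(2.0 * (full.loglik - reduced.loglik), 0.0)
        df = len(cols)
        rows.append(
            {"group": name, "statistic": stat, "df": df,
             "pvalue": float(stats.chi2.sf(stat, df))}
        )
    return pd.DataFrame(rows).set_index("group")


def vif(X) -> pd.Series:
    """Variance inflation factor per predictor.

    VIF_j = 1/(1 - R2_j), with R2_j from regressing predictor j on the
    others (with intercept).  Exactly collinear predictors report ``inf``.
    The conventional screening threshold is 10.
    """
    xdf = X.frame if isinstance(X, CovariateMatrix) else pd.DataFrame(X)
    xdf = xdf.drop(columns=["const"], errors="ignore").astype(float)
    if xdf.shape[1] < 2:
        raise InputError("VIF needs at least two predictors")
    out = {}
    for col in xdf.columns:
        others = sm.add_constant(xdf.drop(columns=[col]))
        r2 = sm.OLS(xdf[col], others).fit().rsquared
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


def backward_aic(y, X, family: str = "gaussian", weights=None):
    """Backward stepwise selection by AIC, one predictor per step.

    Starting from the full model, repeatedly drop the single predictor
    whose removal most decreases AIC; stop when no removal decreases it.
    The intercept is never dropped.  Returns ``(best fit, path)`` where
    ``path`` records each step's action and AIC.
    """

    def _fit(xdf):
        if family == "gaussian":
            return fit_linear(y, xdf)
        if family == "nb":
            return fit_nb_glm(y, xdf, weights=weights)
        raise InputError(f"unknown family {family!r}")

    y = np.asarray(y, dtype=float)
    xdf = _as_model_matrix(X, len(y))
    current = _fit(xdf)
    path = [{"step": 0, "dropped": "<full model>", "aic": current.aic}]
    step = 0
    while True:
        candidates = [c for c in xdf.columns if c != "const"]
        if not candidates:
            break
        trials = {c: _fit(xdf.drop(columns=[c])) for c in candidates}
        best_col = min(trials, key=lambda c: trials[c].aic)
        if trials[best_col].aic >= current.aic:
            break
        step += 1
        xdf = xdf.drop(columns=[best_col])
        current = trials[best_col]
        path.append({"step": step, "dropped": best_col, "aic": current.aic})
    return current, pd.DataFrame(path)


def pca_reduce(table: pd.DataFrame, anchor: str) -> PCAResult:
    """First principal component of a standardized variable block.

    Variables are z-scored (correlation-matrix PCA — the blocks mix units
    such as pH, percent and mg/kg, so covariance PCA would be dominated by
    scale).  The axis sign is oriented so that the ``anchor`` variable's
    loading is positive, fixing the interpretation of the score.
    """
    from sklearn.decomposition import PCA

    table = pd.DataFrame(table)
    if table.shape[1] < 2 or table.shape[0] < 3:
        raise InputError("PCA needs >= 2 variables and >= 3 samples")
    if table.isna().any().any():
        raise InputError("PCA block contains missing values")
    if anchor not in table.columns:
        raise InputError(f"anchor {anchor!r} not among block variables")
    sds = table.std(ddof=1)
    if (sds == 0).any():
        bad = sds.index[sds == 0][0]
        raise DegenerateInputError(f"variable {bad!r} is constant")
    z = (table - table.mean()) / sds
    pca = PCA(n_components=1)
    scores = pca.fit_transform(z.to_numpy())[:, 0]
    loadings = pca.components_[0]
    if loadings[table.columns.get_loc(anchor)] < 0:
        loadings = -loadings
        scores = -scores
    return PCAResult(
        scores=pd.Series(scores, index=table.index, name="PC1"),
        loadings=pd.Series(loadings, index=table.columns, name="loading"),
        var_fraction=float(pca.explained_variance_ratio_[0]),
        anchor=anchor,
    )
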