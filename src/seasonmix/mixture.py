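"""Finite mixtures of negative-binomial regressions over genus count series.

Each genus is a latent draw from one of K mixture components; a component
is a log-link NB regression of counts on the standardized covariates
(Sc, Ss, Ele, Dep) with its own coefficient vector and dispersion.
Responsibilities are computed at the *genus* level: the likelihood of a
genus under a component is the product over all of its samples, so the
whole count series of a genus is assigned to one component.  This matches
the use of the clusters downstream, where each cluster is a set of genera
whose abundance-rank range and pooled regression are reported.

Fitting is EM: the E-step computes genus-by-component responsibilities in
the log domain; the M-step updates mixing weights and refits each
component by responsibility-weighted NB regression.  Because every genus
shares the same covariate rows, the weighted regression collapses to an
S-row GLM on responsibility-averaged counts (identical score equations),
which keeps the M-step cheap at any number of genera.  The dispersion of
each component is profiled by maximum likelihood on the full weighted
table, using the fact that the Gamma-function terms depend on the data
only through the multiset of observed count values.

Model selection sweeps K (2..20 by default) with random restarts per K
and picks the minimum BIC; BIC uses N = genera x samples observations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special

from .design import CovariateMatrix
from .exceptions import FitError, InputError
from .prep import rank_abundance, validate_counts
from .regression import THETA_BOUNDS, deviance_explained, fit_nb_glm
from .simulate import as_rng

logger = logging.getLogger(__name__)

__all__ = [
    "MixtureModel",
    "ClusterResult",
    "em_fit",
    "restart_best",
    "sweep_k",
    "assign_clusters",
    "cluster_effect_table",
    "cluster_result",
]


@dataclass
class MixtureModel:
    """A fitted K-component NB-regression mixture."""

    k: int
    weights: np.ndarray                 # mixing weights, sum to 1
    coefs: pd.DataFrame                 # K x (const, Sc, Ss, Ele, Dep)
    thetas: np.ndarray                  # per-component dispersions
    responsibilities: pd.DataFrame      # genus x component, rows sum to 1
    loglik: float
    n_params: int
    bic: float
    n_iter: int
    converged: bool
    loglik_trace: list[float] = field(default_factory=list)
    restart_index: int | None = None
    restart_logliks: list[float] | None = None
    k_requested: int | None = None      # before any component elimination
    n_obs: int = 0


@dataclass
class ClusterResult:
    """Hard genus clusters with their per-cluster effect tables."""

    labels: pd.Series                   # genus -> cluster in 1..K
    effects: pd.DataFrame               # per-cluster coefficients/p/DeltaD/D
    rank_ranges: pd.DataFrame | None = None


def _coerce_X(X, n_samples: int) -> pd.DataFrame:
    if isinstance(X, CovariateMatrix):
        xdf = X.design_matrix()
    else:
        xdf = pd.DataFrame(X).copy()
        if "const" not in xdf.columns:
            xdf.insert(0, "const", 1.0)
    if len(xdf) != n_samples:
        raise InputError(
            f"covariate matrix has {len(xdf)} rows but the count table has "
            f"{n_samples} samples"
        )
    return xdf.astype(float)


def _moment_theta(y: np.ndarray) -> float:
    m = y.mean()
    v = y.var()
    if v <= m or m == 0:
        return THETA_BOUNDS[1]
    return float(np.clip(m * m / (v - m), *THETA_BOUNDS))


class _EmWorkspace:
    """Precomputed count-table quantities reused across EM iterations."""

    def __init__(self, Y: np.ndarray):
        self.Y = Y
        self.G, self.S = Y.shape
        u, inv = np.unique(Y, return_inverse=True)
        self.u = u.astype(float)
        self.inv_flat = inv.reshape(-1)
        self.inv2d = inv.reshape(Y.shape)
        self.gammaln_yp1_row = special.gammaln(Y + 1.0).sum(axis=1)

    def row_gammaln(self, theta: float) -> np.ndarray:
        """Per-genus sum over samples of gammaln(y + theta)."""
        return special.gammaln(self.u + theta)[self.inv2d].sum(axis=1)

    def profile_theta(self, w: np.ndarray, mu: np.ndarray) -> float:
        """Maximize sum_g w_g sum_s loglik(y_gs; mu_s, theta) over theta.

        Collapses the gammaln(y+theta) sum onto unique count values with
        weights c_v = sum over cells holding value v of that genus's w.
        """
        W = w.sum()
        c = np.bincount(
            self.inv_flat, weights=np.repeat(w, self.S), minlength=len(self.u)
        )
        t = w @ self.Y  # weighted count total per sample

        def neg(lt):
            theta = np.exp(lt)
            val = (
                c @ special.gammaln(self.u + theta)
                - W * self.S * special.gammaln(theta)
                + theta * W * np.log(theta / (theta + mu)).sum()
                + t @ np.log(mu / (theta + mu))
            )
            return -val

        res = optimize.minimize_scalar(
            neg,
            bounds=(np.log(THETA_BOUNDS[0]), np.log(THETA_BOUNDS[1])),
            method="bounded",
            options={"xatol": 1e-8},
        )
        return float(np.exp(res.x))

    def component_loglik(self, mu: np.ndarray, theta: float) -> np.ndarray:
        """Per-genus log-likelihood under one component (sum over samples)."""
        return (
            self.row_gammaln(theta)
            - self.S * special.gammaln(theta)
            - self.gammaln_yp1_row
            + theta * np.log(theta / (theta + mu)).sum()
            + self.Y @ np.log(mu / (theta + mu))
        )


def em_fit(table: pd.DataFrame, X, k: int, seed=None, tol: float = 1e-6,
           max_iter: int = 500) -> MixtureModel:
    """Fit a K-component NB-regression mixture by EM from one random start.

    Initialization assigns each genus uniformly at random to one of the K
    components (hard partition) and takes an M-step.  Components whose
    mixing weight collapses below 1/(2G) are eliminated and the fit
    continues with K-1 (logged).  The log-likelihood trace is recorded and
    is non-decreasing up to numerical tolerance.
    """
    table = validate_counts(table)
    Y = table.to_numpy(dtype=float)
    G, S = Y.shape
    if k < 1:
        raise InputError("k must be >= 1")
    if k > G:
        raise InputError(f"k={k} exceeds the number of genera ({G})")
    xdf = _coerce_X(X, S)
    Xd = xdf.to_numpy()
    p = Xd.shape[1]
    rng = as_rng(seed)
    ws = _EmWorkspace(Y)

    # random hard partition; make sure every component starts non-empty
    labels = rng.integers(0, k, size=G)
    for comp in range(k):
        if not (labels == comp).any():
            labels[rng.integers(0, G)] = comp
    R = np.zeros((G, k))
    R[np.arange(G), labels] = 1.0

    betas = np.zeros((k, p))
    thetas = np.array([_moment_theta(Y[labels == comp]) for comp in range(k)])
    have_start = np.zeros(k, dtype=bool)
    mus = np.zeros((k, S))
    k_requested = k

    trace: list[float] = []
    ll = -np.inf
    converged = False
    n_iter = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for n_iter in range(1, max_iter + 1):
            # ---- M-step -------------------------------------------------
            pi = R.mean(axis=0)
            alive = pi >= 1.0 / (2.0 * G)
            if not alive.all():
                logger.info(
                    "em_fit: eliminating %d collapsed component(s), k %d -> %d",
                    (~alive).sum(), k, int(alive.sum()),
                )
                R = R[:, alive]
                R /= R.sum(axis=1, keepdims=True)
                betas, thetas, mus = betas[alive], thetas[alive], mus[alive]
                have_start = have_start[alive]
                k = int(alive.sum())
                pi = R.mean(axis=0)
            for comp in range(k):
                w = R[:, comp]
                wsum = w.sum()
                ybar = (w @ Y) / wsum
                try:
                    model = sm.GLM(
                        ybar, Xd,
                        family=sm.families.NegativeBinomial(
                            alpha=1.0 / thetas[comp]
                        ),
                    )
                    res = model.fit(
                        start_params=betas[comp] if have_start[comp] else None,
                        maxiter=200,
                    )
                except Exception as exc:  # perfect separation, singularities
                    raise FitError(f"component refit failed: {exc}") from exc
                betas[comp] = np.asarray(res.params)
                have_start[comp] = True
                mu = np.clip(np.asarray(res.mu), 1e-12, 1e12)
                thetas[comp] = ws.profile_theta(w, mu)
                mus[comp] = mu
            # ---- E-step -------------------------------------------------
            logf = np.column_stack(
                [ws.component_loglik(mus[comp], thetas[comp]) for comp in range(k)]
            )
            logpost = np.log(pi)[None, :] + logf
            row_ll = special.logsumexp(logpost, axis=1)
            new_ll = float(row_ll.sum())
            R = np.exp(logpost - row_ll[:, None])
            trace.append(new_ll)
            if np.isfinite(ll) and abs(new_ll - ll) < tol * (abs(ll) + 1.0):
                ll = new_ll
                converged = True
                break
            ll = new_ll
    if not converged:
        logger.warning(
            "em_fit: no convergence in %d iterations (best loglik %.6g)",
            max_iter, ll,
        )

    n_params = (k - 1) + k * (p + 1)
    n_obs = G * S
    genus_index = table.index
    comp_index = pd.RangeIndex(1, k + 1, name="component")
    return MixtureModel(
        k=k,
        weights=R.mean(axis=0),
        coefs=pd.DataFrame(betas, columns=xdf.columns, index=comp_index),
        thetas=thetas.copy(),
        responsibilities=pd.DataFrame(R, index=genus_index, columns=comp_index),
        loglik=ll,
        n_params=n_params,
        bic=-2.0 * ll + n_params * np.log(n_obs),
        n_iter=n_iter,
        converged=converged,
        loglik_trace=trace,
        k_requested=k_requested,
        n_obs=n_obs,
    )


def restart_best(table: pd.DataFrame, X, k: int, n_restarts: int = 5,
                 seed=None, **em_kwargs) -> MixtureModel:
    """Run EM from ``n_restarts`` random initializations; keep the best.

    The winner is the restart with the highest final log-likelihood.
    Restart seeds are spawned deterministically from ``seed``.
    """
    if n_restarts < 1:
        raise InputError("n_restarts must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_restarts)
    best = None
    errors = []
    logliks = []
    for i, child in enumerate(children):
        try:
            model = em_fit(table, X, k, seed=np.random.default_rng(child), **em_kwargs)
        except FitError as exc:
            errors.append(f"restart {i}: {exc}")
            continue
        logliks.append(model.loglik)
        if best is None or model.loglik > best.loglik:
            model.restart_index = i
            best = model
    if best is None:
        raise FitError("all restarts failed: " + "; ".join(errors))
    best.restart_logliks = logliks
    return best


def sweep_k(table: pd.DataFrame, X, k_range=range(2, 21), n_restarts: int = 5,
            seed=None, **em_kwargs):
    """Fit mixtures over a range of K and select the minimum-BIC model.

    Returns ``(best model, curve)`` where ``curve`` lists BIC, loglik and
    the effective K (after any component elimination) for every candidate.
    """
    k_range = list(k_range)
    if not k_range:
        raise InputError("k_range is empty")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(k_range))
    rows = []
    best = None
    for k, child in zip(k_range, children):
        model = restart_best(table, X, k, n_restarts=n_restarts, seed=child,
                             **em_kwargs)
        rows.append(
            {
                "k_requested": k,
                "k_effective": model.k,
                "loglik": model.loglik,
                "bic": model.bic,
                "converged": model.converged,
                "n_iter": model.n_iter,
            }
        )
        if best is None or model.bic < best.bic:
            best = model
    curve = pd.DataFrame(rows).set_index("k_requested")
    return best, curve


def assign_clusters(model: MixtureModel) -> pd.Series:
    """Hard labels in 1..K by maximum responsibility (ties -> lowest index)."""
    r = model.responsibilities.to_numpy()
    return pd.Series(
        np.argmax(r, axis=1) + 1, index=model.responsibilities.index,
        name="cluster",
    )


def cluster_effect_table(model: MixtureModel, table: pd.DataFrame, X,
                         groups=None) -> pd.DataFrame:
    """Per-cluster pooled NB regressions (printed effect table).

    For each hard cluster, the member genera's observations are pooled
    into one NB regression on the covariates; the table reports its
    coefficients, Wald p-values, per-covariate explained-deviance drops
    (Delta D) and total D.  These post-hoc refits — not the soft-weighted
    component parameters — are what the printed table shows, so p-values
    and deviances are those of an ordinary single regression; the
    component parameters remain available on the model object.
    """
    table = validate_counts(table)
    labels = assign_clusters(model)
    xdf = _coerce_X(X, table.shape[1])
    covs = [c for c in xdf.columns if c != "const"]
    groups = groups or {c: [c] for c in covs}
    rows = []
    for cluster in sorted(labels.unique()):
        members = labels.index[labels == cluster]
        if len(members) < 2:
            logger.warning(
                "cluster %d has %d member genus(era); fitting anyway",
                cluster, len(members),
            )
        sub = table.loc[members].to_numpy(dtype=float)
        y = sub.reshape(-1)
        xrep = pd.concat([xdf] * len(members), ignore_index=True)
        fit = fit_nb_glm(y, xrep)
        d, delta = deviance_explained(fit, groups)
        row = {"cluster": int(cluster), "n_genera": len(members)}
        for c in covs:
            row[f"coef_{c}"] = fit.params[c]
            row[f"p_{c}"] = fit.pvalues[c]
        for name, dd in delta.items():
            row[f"deltaD_{name}"] = dd
        row["D"] = d
        row["theta"] = fit.theta
        rows.append(row)
    return pd.DataFrame(rows).set_index("cluster")


def cluster_result(model: MixtureModel, table: pd.DataFrame, X) -> ClusterResult:
    """Bundle hard labels, effect tables and abundance-rank ranges."""
    labels = assign_clusters(model)
    effects = cluster_effect_table(model, table, X)
    _, ranges = rank_abundance(table, labels)
    return ClusterResult(labels=labels, effects=effects, rank_ranges=ranges)
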