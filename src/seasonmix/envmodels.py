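"""Environmental GLM stage.

Regresses community responses (genus richness, total abundance, and the
per-sample sequence counts of each genus cluster) on the four reduced
environmental predictors — soil temperature (ST, degC), gravimetric soil
water content (SWC, %), and the first principal components of the soil
chemistry and plant trait blocks (Soil PC1, Plant PC1) — with backward
AIC selection and explained-deviance decomposition.  Richness and
abundance are modeled Gaussian, cluster counts negative-binomial.

A companion analysis regresses each environmental variable on the design
covariates (Sc, Ss, Ele, Dep) to characterize its seasonal/spatial
structure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import CovariateMatrix
from .exceptions import InputError
from .regression import (
    PCAResult,
    backward_aic,
    deviance_explained,
    fit_linear,
    pca_reduce,
    vif,
)
from .simulate import PLANT_BLOCK, SOIL_BLOCK

ENV_PREDICTORS = ["ST", "SWC", "SoilPC1", "PlantPC1"]

#: PCA sign anchors: the soil axis is oriented by total carbon (a fertility
#: gradient reads positive), the plant axis by canopy openness.
SOIL_ANCHOR = "total_C"
PLANT_ANCHOR = "canopy_openness"

GAUSSIAN_RESPONSES = ("richness", "copies")
NB_RESPONSES = ("cluster_counts",)


def reduce_environment(env: pd.DataFrame, soil_block=None, plant_block=None):
    """Build the four-predictor frame {ST, SWC, SoilPC1, PlantPC1}.

    Returns ``(predictors, soil_pca, plant_pca)``; the PCA results carry
    loadings and variance fractions for reporting.
    """
    soil_block = soil_block or [c for c in SOIL_BLOCK if c in env.columns]
    plant_block = plant_block or [c for c in PLANT_BLOCK if c in env.columns]
    for col in ("ST", "SWC"):
        if col not in env.columns:
            raise InputError(f"environment table lacks {col!r}")
    soil_pca = pca_reduce(env[soil_block], anchor=SOIL_ANCHOR)
    plant_pca = pca_reduce(env[plant_block], anchor=PLANT_ANCHOR)
    pred = pd.DataFrame(
        {
            "ST": env["ST"].astype(float),
            "SWC": env["SWC"].astype(float),
            "SoilPC1": soil_pca.scores,
            "PlantPC1": plant_pca.scores,
        },
        index=env.index,
    )
    return pred, soil_pca, plant_pca


def response_family(kind: str) -> str:
    """Family dispatch: gaussian for richness/copies, NB for cluster counts."""
    if kind in GAUSSIAN_RESPONSES:
        return "gaussian"
    if kind in NB_RESPONSES:
        return "nb"
    raise InputError(
        f"unsupported response kind {kind!r}; expected one of "
        f"{GAUSSIAN_RESPONSES + NB_RESPONSES}"
    )


def fit_env_glms(responses: dict[str, tuple[str, pd.Series]],
                 env_predictors: pd.DataFrame) -> pd.DataFrame:
    """Backward-AIC GLMs of each response on {ST, SWC, SoilPC1, PlantPC1}.

    ``responses`` maps a response name to ``(kind, series)`` with kind in
    {"richness", "copies", "cluster_counts"}.  Predictors eliminated by
    the backward selection appear as missing values; retained predictors
    report their coefficient and Delta D, plus the model's total D.  A
    VIF screen over the full predictor set is included per response
    (reported, not enforced; the conventional threshold is 10).
    """
    vifs = vif(env_predictors)
    rows = []
    for name, (kind, y) in responses.items():
        family = response_family(kind)
        y = pd.Series(y).loc[env_predictors.index]
        fit, path = backward_aic(y.to_numpy(), env_predictors, family=family)
        retained = [c for c in fit._X.columns if c != "const"]
        if retained:
            d, delta = deviance_explained(fit, {c: [c] for c in retained})
        else:
            d, delta = 0.0, pd.Series(dtype=float)
        row = {"response": name, "family": family, "D": d,
               "n_dropped": len(path) - 1, "max_vif": float(vifs.max())}
        for c in env_predictors.columns:
            row[f"coef_{c}"] = fit.params.get(c, np.nan)
            row[f"deltaD_{c}"] = delta.get(c, np.nan)
        rows.append(row)
    return pd.DataFrame(rows).set_index("response")


def cluster_count_responses(table: pd.DataFrame,
                            labels: pd.Series) -> dict[str, tuple[str, pd.Series]]:
    """Per-sample total counts of each cluster, as NB responses."""
    out = {}
    for cluster in sorted(pd.Series(labels).unique()):
        members = labels.index[labels == cluster]
        out[f"cluster_{cluster}"] = (
            "cluster_counts",
            table.loc[members].sum(axis=0),
        )
    return out


def env_on_design(env: pd.DataFrame, X: CovariateMatrix,
                  variables=("ST", "SWC", "SoilPC1", "PlantPC1")) -> pd.DataFrame:
    """Linear regressions of environmental variables on (Sc, Ss, Ele, Dep).

    Returns one row per variable with coefficients, p-values and R2 — the
    seasonal/spatial sign structure of each driver.
    """
    rows = []
    for var in variables:
        if var not in env.columns:
            raise InputError(f"environment table lacks {var!r}")
        fit = fit_linear(env[var].loc[X.sample_ids].to_numpy(), X)
        row = {"variable": var, "R2": fit.r_squared}
        for c in X.frame.columns:
            row[f"coef_{c}"] = fit.params[c]
            row[f"p_{c}"] = fit.pvalues[c]
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")


__all__ = [
    "ENV_PREDICTORS",
    "reduce_environment",
    "response_family",
    "fit_env_glms",
    "cluster_count_responses",
    "env_on_design",
    "PCAResult",
]
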