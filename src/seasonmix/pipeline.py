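"""End-to-end orchestration: simulate/read -> prep -> diversity regressions
-> mixture clustering -> indicator genera -> environmental GLMs.

The report bundle mirrors the standard presentation of such analyses:

* ``diversity_regressions`` — richness and total-abundance responses on
  (Sc, Ss, Ele, Dep) with coefficients, p-values, per-covariate Delta R2
  and R2, plus group likelihood-ratio importance tests
  (``diversity_importance``) and fitted seasonal peak/trough dates
  (``seasonal_peaks``);
* ``cluster_effects`` — per-cluster pooled NB regressions (coefficient,
  p, Delta D, D) for the BIC-selected mixture, with ``bic_curve``,
  ``cluster_labels``, ``cluster_rank_ranges`` and predicted per-cluster
  seasonal trajectories (``cluster_trajectories``);
* ``indicator_genera`` — per-genus indicator values and permutation p;
* ``env_glms`` — backward-AIC GLMs of community responses on ST, SWC,
  Soil PC1 and Plant PC1, and ``env_on_design`` for the drivers'
  seasonal/spatial sign structure.

Everything is deterministic given the master seed, which is expanded into
independent substreams per stage.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import logging
import os
import platform
import time

import numpy as np
import pandas as pd
import yaml

from . import io as smio
from .design import DEFAULT_ORIGIN, SEASON_GROUPS, build_covariates, peak_day
from .envmodels import (
    cluster_count_responses,
    env_on_design,
    fit_env_glms,
    reduce_environment,
)
from .exceptions import InputError, NoSeasonalityError
from .indicator import indicator_table
from .mixture import MixtureModel, cluster_result, sweep_k
from .prep import genus_richness, rarefy
from .regression import fit_linear, lrt_importance, r2_decomposition
from .simulate import (
    SimulationParams,
    make_design,
    simulate_community,
    simulate_environment,
)

logger = logging.getLogger(__name__)

STAGES = ("community", "environment", "rarefy", "mixture", "indicator")


@dataclasses.dataclass
class AnalysisConfig:
    """Configuration of one pipeline run.

    Exactly one of (``counts_path`` + ``metadata_path``) or ``simulation``
    must be provided.
    """

    counts_path: str | None = None
    metadata_path: str | None = None
    env_path: str | None = None
    simulation: SimulationParams | None = None
    origin_date: _dt.date = DEFAULT_ORIGIN
    rarefaction_depth: int | None = None
    k_min: int = 2
    k_max: int = 8
    n_restarts: int = 5
    n_permutations: int = 99
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        has_files = self.counts_path is not None and self.metadata_path is not None
        has_sim = self.simulation is not None
        if has_files == has_sim:
            raise InputError(
                "config needs exactly one of input paths (counts + metadata) "
                "or a simulation block"
            )
        if self.k_min < 1 or self.k_max < self.k_min:
            raise InputError("need 1 <= k_min <= k_max")

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        sim = d.pop("simulation", None)
        if sim is not None:
            sim = SimulationParams(**sim) if isinstance(sim, dict) else sim
        origin = d.pop("origin_date", DEFAULT_ORIGIN)
        if isinstance(origin, str):
            origin = _dt.date.fromisoformat(origin)
        return cls(simulation=sim, origin_date=origin, **d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def echo(self) -> dict:
        out = dataclasses.asdict(self)
        if self.simulation is not None:
            sim = {}
            for k, v in dataclasses.asdict(self.simulation).items():
                if isinstance(v, np.ndarray):
                    v = v.tolist()
                sim[k] = v
            out["simulation"] = sim
        return json.loads(json.dumps(out, default=str))


def config_hash(config: AnalysisConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.echo(), sort_keys=True).encode()
    ).hexdigest()[:12]


def _stage_seeds(seed: int) -> dict[str, np.random.SeedSequence]:
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return dict(zip(STAGES, children))


def diversity_regressions(responses: dict[str, pd.Series], cov) -> dict[str, pd.DataFrame]:
    """Linear seasonal/spatial regressions for per-sample responses.

    Produces the main coefficient table (with per-covariate Delta R2),
    the group LRT importance table, and fitted seasonal extrema.
    """
    main_rows, lrt_rows, peak_rows = [], [], []
    for name, y in responses.items():
        y = pd.Series(y).loc[cov.sample_ids].to_numpy(dtype=float)
        fit = fit_linear(y, cov)
        _, dr2 = r2_decomposition(y, cov)
        row = {"response": name}
        for c in cov.frame.columns:
            row[f"coef_{c}"] = fit.params[c]
            row[f"p_{c}"] = fit.pvalues[c]
            row[f"deltaR2_{c}"] = dr2[c]
        row["R2"] = fit.r_squared
        main_rows.append(row)
        lrt = lrt_importance(y, cov, groups=SEASON_GROUPS)
        for grp, r in lrt.iterrows():
            lrt_rows.append({"response": name, "group": grp, **r.to_dict()})
        try:
            ext = peak_day(
                fit.params["Sc"], fit.params["Ss"],
                sd_sc=cov.sds["Sc"], sd_ss=cov.sds["Ss"],
                origin=cov.origin_date,
            )
            peak_rows.append(
                {
                    "response": name,
                    "peak_date": ext.peak_date.isoformat(),
                    "peak_day_of_year": ext.peak_day_of_year,
                    "peak_month": ext.peak_month,
                    "trough_date": ext.trough_date.isoformat(),
                    "trough_day_of_year": ext.trough_day_of_year,
                    "trough_month": ext.trough_month,
                }
            )
        except NoSeasonalityError:
            logger.warning("response %r has no seasonal component", name)
    return {
        "diversity_regressions": pd.DataFrame(main_rows).set_index("response"),
        "diversity_importance": pd.DataFrame(lrt_rows).set_index(
            ["response", "group"]
        ),
        "seasonal_peaks": pd.DataFrame(peak_rows).set_index("response"),
    }


def cluster_trajectories(model: MixtureModel, cov, design: pd.DataFrame) -> pd.DataFrame:
    """Predicted per-cluster mean counts across the design (component fits)."""
    xmat = cov.design_matrix().to_numpy()
    mu = np.exp(model.coefs.to_numpy() @ xmat.T)  # K x S
    frames = []
    meta = design.set_index("sample_id")
    for ki, comp in enumerate(model.coefs.index):
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": cov.sample_ids,
                    "cluster": comp,
                    "collection_date": meta.loc[cov.sample_ids, "collection_date"].to_numpy(),
                    "site_id": meta.loc[cov.sample_ids, "site_id"].to_numpy(),
                    "depth_layer": meta.loc[cov.sample_ids, "depth_layer"].to_numpy(),
                    "predicted_mean": mu[ki],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def serialize_model(model: MixtureModel) -> dict:
    """Structured-text representation of a fitted mixture."""
    return {
        "k": int(model.k),
        "k_requested": int(model.k_requested or model.k),
        "weights": model.weights.tolist(),
        "coefficients": {
            str(c): model.coefs.loc[c].to_dict() for c in model.coefs.index
        },
        "thetas": model.thetas.tolist(),
        "loglik": model.loglik,
        "n_params": int(model.n_params),
        "bic": model.bic,
        "n_iter": int(model.n_iter),
        "converged": bool(model.converged),
        "restart_index": model.restart_index,
        "n_obs": int(model.n_obs),
    }


def run_analysis(config: AnalysisConfig):
    """Run the full pipeline; returns ``(bundle, manifest)``.

    ``bundle`` maps table names to DataFrames; ``manifest`` is a
    machine-readable run record (config echo, seeds, versions, timing).
    """
    t0 = time.monotonic()
    seeds = _stage_seeds(config.seed)
    bundle: dict[str, pd.DataFrame] = {}

    # ---- inputs -----------------------------------------------------------
    if config.simulation is not None:
        params = config.simulation
        design = make_design(params)
        counts, truth = simulate_community(
            design, params, seed=np.random.default_rng(seeds["community"])
        )
        env, _latent = simulate_environment(
            design, params, seed=np.random.default_rng(seeds["environment"])
        )
        origin = params.origin_date
        bundle["true_labels"] = truth.labels.to_frame()
    else:
        counts = smio.read_counts(config.counts_path)
        design = smio.read_design(config.metadata_path)
        env = smio.read_env(config.env_path) if config.env_path else None
        counts, design, env = smio.align_tables(counts, design, env)
        origin = config.origin_date
        truth = None

    # ---- prep -------------------------------------------------------------
    if config.rarefaction_depth:
        counts = rarefy(
            counts, config.rarefaction_depth,
            seed=np.random.default_rng(seeds["rarefy"]),
        )
        design = design[design["sample_id"].isin(counts.columns)].reset_index(
            drop=True
        )
        if env is not None:
            env = env.loc[counts.columns]
    cov = build_covariates(design, origin)
    counts = counts[cov.sample_ids]

    richness = genus_richness(counts)
    abundance = counts.sum(axis=0).rename("total_reads")
    bundle["sample_summaries"] = pd.DataFrame(
        {"richness": richness, "total_reads": abundance}
    )

    # ---- diversity regressions -------------------------------------------
    bundle.update(
        diversity_regressions(
            {"richness": richness, "total_reads": abundance}, cov
        )
    )

    # ---- mixture clustering ----------------------------------------------
    model, curve = sweep_k(
        counts, cov, k_range=range(config.k_min, config.k_max + 1),
        n_restarts=config.n_restarts, seed=seeds["mixture"], tol=config.tol,
    )
    clusters = cluster_result(model, counts, cov)
    bundle["bic_curve"] = curve
    bundle["cluster_effects"] = clusters.effects
    bundle["cluster_labels"] = clusters.labels.to_frame()
    bundle["cluster_rank_ranges"] = clusters.rank_ranges
    bundle["cluster_trajectories"] = cluster_trajectories(model, cov, design)

    # ---- indicator genera --------------------------------------------------
    ind = indicator_table(
        counts, clusters.labels, n_permutations=config.n_permutations,
        seed=np.random.default_rng(seeds["indicator"]),
    )
    bundle["indicator_genera"] = ind
    bundle["indicator_top"] = ind[ind["top"]].copy()

    # ---- environmental GLMs ------------------------------------------------
    if env is not None:
        predictors, soil_pca, plant_pca = reduce_environment(env)
        responses = {
            "richness": ("richness", richness),
            "total_reads": ("copies", abundance),
            **cluster_count_responses(counts, clusters.labels),
        }
        bundle["env_glms"] = fit_env_glms(responses, predictors)
        env_full = env.copy()
        env_full["SoilPC1"] = predictors["SoilPC1"]
        env_full["PlantPC1"] = predictors["PlantPC1"]
        bundle["env_on_design"] = env_on_design(env_full, cov)
        bundle["env_pca"] = pd.DataFrame(
            {
                "block": ["soil"] * len(soil_pca.loadings)
                + ["plant"] * len(plant_pca.loadings),
                "variable": list(soil_pca.loadings.index)
                + list(plant_pca.loadings.index),
                "loading": list(soil_pca.loadings) + list(plant_pca.loadings),
                "var_fraction": [soil_pca.var_fraction] * len(soil_pca.loadings)
                + [plant_pca.var_fraction] * len(plant_pca.loadings),
            }
        ).set_index(["block", "variable"])

    manifest = {
        "config": config.echo(),
        "config_hash": config_hash(config),
        "seed": config.seed,
        "selected_k": int(model.k),
        "model": serialize_model(model),
        "tables": sorted(bundle),
        "versions": _versions(),
        "wall_clock_s": round(time.monotonic() - t0, 3),
    }
    return bundle, manifest


def _versions() -> dict:
    import scipy
    import sklearn
    import statsmodels

    return {
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
        "sklearn": sklearn.__version__,
    }


def write_report(bundle: dict, manifest: dict, outdir, overwrite: bool = False):
    """Write the bundle as TSVs plus a JSON manifest.

    Refuses to write into a directory that already holds report files
    unless ``overwrite`` is set.  An empty bundle still writes the
    manifest (with a warning).
    """
    os.makedirs(outdir, exist_ok=True)
    existing = [f for f in os.listdir(outdir) if f.endswith((".tsv", ".json"))]
    if existing and not overwrite:
        raise InputError(
            f"output directory {outdir} already contains report files "
            f"(e.g. {existing[0]}); pass overwrite to replace them"
        )
    if not bundle:
        logger.warning("empty bundle: writing manifest only")
    prov = (
        f"seed={manifest.get('seed')} config_hash={manifest.get('config_hash')}"
    )
    written = []
    for name, df in bundle.items():
        path = os.path.join(outdir, f"{name}.tsv")
        smio.write_table(pd.DataFrame(df), path, provenance=prov)
        written.append(f"{name}.tsv")
    manifest = dict(manifest)
    manifest["files"] = sorted(written + ["manifest.json"])
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest["files"]
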