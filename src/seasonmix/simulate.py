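"""Synthetic study generator.

Emulates a crossed field design — three montane survey sites at distinct
elevations, monthly soil sampling over one year, four depth layers (144
samples by default) — together with seasonally and elevationally structured
environmental drivers and a genus-by-sample count table drawn from a known
finite mixture of negative-binomial regressions on the standardized
covariates (Sc, Ss, Ele, Dep).

Because the generating mixture is known, every downstream stage (clustering,
effect tables, indicator tests, environmental GLMs) can be checked for
parameter and label recovery.  The ground truth is returned alongside the
counts as :class:`SyntheticTruth`.

The negative binomial is parameterized by mean ``mu`` and dispersion
``theta`` with variance ``mu + mu**2/theta``; counts are drawn as a
gamma–Poisson mixture, which is exact in this parameterization and remains
stable in the Poisson limit ``theta -> inf``.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DEFAULT_ORIGIN, DEPTH_LAYERS, build_covariates, validate_design
from .exceptions import InputError

__all__ = [
    "SimulationParams",
    "EnvParams",
    "SyntheticTruth",
    "make_design",
    "simulate_environment",
    "simulate_community",
]


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed / SeedSequence / Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class EnvParams:
    """Parameters of the environmental-driver generator.

    Each driver is a linear response to the raw harmonics, elevation and
    depth plus Gaussian noise; signs mirror the structure the analysis is
    meant to detect: soil temperature (ST, degC) rises in summer and falls
    with elevation; gravimetric soil water content (SWC, %) falls in early
    summer and with depth but rises with elevation; the latent soil
    fertility score falls with Ss and depth and rises with elevation; the
    latent plant phenology score falls with Sc, Ss and elevation.
    """

    st_base: float = 9.0
    st_amp_sc: float = 6.0       # degC per unit raw cosine score
    st_amp_ss: float = 6.0
    st_lapse_per_m: float = 0.005  # degC lost per metre of elevation
    st_noise_sd: float = 1.0

    swc_base: float = 45.0
    swc_sc: float = -10.0
    swc_ele_per_m: float = 0.01
    swc_dep_per_cm: float = -0.6
    swc_noise_sd: float = 5.0

    fert_ss: float = -1.0
    fert_dep_per_cm: float = -0.05
    fert_ele_per_m: float = 0.001
    fert_noise_sd: float = 0.5

    plant_sc: float = -1.0
    plant_ss: float = -1.0
    plant_ele_per_m: float = -0.001
    plant_noise_sd: float = 0.5

    #: sd of the measurement noise added to each observed soil/plant
    #: chemistry variable on top of its latent-score loading
    obs_noise_sd: float = 0.4


def _default_betas() -> np.ndarray:
    # (intercept, Sc, Ss, Ele, Dep) per component; effect magnitudes on
    # standardized covariates chosen in the 0.2-1.2 range typical of
    # genus-level count regressions, with distinct sign patterns so the
    # components occupy different seasonal/spatial niches.
    return np.array(
        [
            [3.0, 0.0, 0.9, -0.4, 0.2],
            [2.5, -0.8, 0.0, 0.9, -0.6],
            [3.5, 0.5, -0.7, 0.0, 1.2],
        ]
    )


@dataclass
class SimulationParams:
    """Full parameter set for the synthetic study."""

    site_elevations_m: dict[str, float] = field(
        default_factory=lambda: {"high": 1831.8, "mid": 1334.2, "low": 880.4}
    )
    n_months: int = 12
    depth_layers: tuple[str, ...] = DEPTH_LAYERS
    origin_date: _dt.date = DEFAULT_ORIGIN
    n_genera: int = 500
    mixing_weights: np.ndarray = field(
        default_factory=lambda: np.array([0.40, 0.35, 0.25])
    )
    component_betas: np.ndarray = field(default_factory=_default_betas)
    component_thetas: np.ndarray = field(default_factory=lambda: np.array([5.0, 5.0, 5.0]))
    genus_offset_sd: float = 0.0
    env: EnvParams = field(default_factory=EnvParams)

    def __post_init__(self):
        self.mixing_weights = np.asarray(self.mixing_weights, dtype=float)
        self.component_betas = np.asarray(self.component_betas, dtype=float)
        self.component_thetas = np.asarray(self.component_thetas, dtype=float)
        k = self.k_true
        if not np.isclose(self.mixing_weights.sum(), 1.0):
            raise InputError("mixing weights must sum to 1")
        if (self.mixing_weights <= 0).any():
            raise InputError("mixing weights must be positive")
        if self.component_betas.shape != (k, 5):
            raise InputError(
                f"component_betas must be ({k}, 5) for (intercept, Sc, Ss, Ele, Dep)"
            )
        if self.component_thetas.shape != (k,) or (self.component_thetas <= 0).any():
            raise InputError("component_thetas must be positive, one per component")
        elev = list(self.site_elevations_m.values())
        if len(set(elev)) != len(elev):
            raise InputError("site elevations must be distinct")
        if self.genus_offset_sd < 0:
            raise InputError("genus_offset_sd must be >= 0")

    @property
    def k_true(self) -> int:
        return len(self.mixing_weights)


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated community."""

    labels: pd.Series          # component per genus, values in 1..K
    betas: pd.DataFrame        # K x (const, Sc, Ss, Ele, Dep)
    thetas: np.ndarray
    weights: np.ndarray
    offsets: pd.Series         # per-genus log-abundance offsets

    @property
    def k_true(self) -> int:
        return len(self.weights)


def make_design(params: SimulationParams | None = None) -> pd.DataFrame:
    """Enumerate the full site x month x depth crossing as a design table.

    Dates are monthly from ``origin_date``.  The default parameters yield
    3 x 12 x 4 = 144 rows.
    """
    params = params or SimulationParams()
    if not params.site_elevations_m:
        raise InputError("need at least one site")
    if params.n_months < 1:
        raise InputError("need at least one month")
    if not params.depth_layers:
        raise InputError("need at least one depth layer")
    origin = pd.Timestamp(params.origin_date)
    dates = [
        (origin + pd.DateOffset(months=m)).date() for m in range(params.n_months)
    ]
    rows = []
    for site, elev in params.site_elevations_m.items():
        for date in dates:
            for layer in params.depth_layers:
                rows.append(
                    {
                        "sample_id": f"{site}_{date:%Y%m%d}_{layer}",
                        "site_id": site,
                        "elevation_m": float(elev),
                        "collection_date": date,
                        "depth_layer": layer,
                    }
                )
    return validate_design(pd.DataFrame(rows))


def simulate_environment(design: pd.DataFrame, params: SimulationParams | None = None,
                         seed=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate environmental drivers and chemistry blocks for a design.

    Returns ``(env, latent)``: ``env`` holds ST, SWC and the soil / plant
    chemistry variables; ``latent`` the underlying fertility and phenology
    scores the chemistry loads on (useful for recovery checks).  Soil
    variables load on the fertility score with the sign structure a PCA
    first axis should recover (positive: C, N, C:N, NO3, PO4, NH4, K;
    negative: pH, NO2, SO4, Ca); plant variables load on the phenology
    score (positive: canopy openness, shoot N; negative: leaf C, leaf N,
    leaf C:N, shoot C, shoot C:N).  SWC is clipped to [0, 100] and
    concentrations to >= 0.
    """
    params = params or SimulationParams()
    design = validate_design(design)
    if design.empty:
        raise InputError("design table is empty")
    rng = as_rng(seed)
    p = params.env

    d = np.array(
        [(x - params.origin_date).days for x in design["collection_date"]], dtype=float
    )
    sc_raw = np.cos(2 * np.pi * d / 365.0)
    ss_raw = np.sin(2 * np.pi * d / 365.0)
    ele = design["elevation_m"].to_numpy(dtype=float)
    dep = design["depth_mid_cm"].to_numpy(dtype=float)
    n = len(design)
    idx = pd.Index(design["sample_id"], name="sample_id")

    st = (
        p.st_base
        + p.st_amp_sc * sc_raw
        + p.st_amp_ss * ss_raw
        - p.st_lapse_per_m * (ele - ele.min())
        + rng.normal(0.0, p.st_noise_sd, n)
    )
    swc = np.clip(
        p.swc_base
        + p.swc_sc * sc_raw
        + p.swc_ele_per_m * (ele - ele.mean())
        + p.swc_dep_per_cm * (dep - dep.mean())
        + rng.normal(0.0, p.swc_noise_sd, n),
        0.0,
        100.0,
    )
    fert = (
        p.fert_ss * ss_raw
        + p.fert_dep_per_cm * (dep - dep.mean())
        + p.fert_ele_per_m * (ele - ele.mean())
        + rng.normal(0.0, p.fert_noise_sd, n)
    )
    plant = (
        p.plant_sc * sc_raw
        + p.plant_ss * ss_raw
        + p.plant_ele_per_m * (ele - ele.mean())
        + rng.normal(0.0, p.plant_noise_sd, n)
    )

    def obs(base, loading, score, sd_scale=1.0, nonneg=True):
        x = base + loading * score + rng.normal(0.0, p.obs_noise_sd * sd_scale, n)
        return np.clip(x, 0.0, None) if nonneg else x

    total_c = obs(8.0, 2.2, fert)
    total_n = obs(0.45, 0.08, fert, sd_scale=0.05)
    total_n = np.clip(total_n, 0.05, None)  # keep the ratio defined
    env = pd.DataFrame(
        {
            "ST": st,
            "SWC": swc,
            "pH": obs(4.8, -0.35, fert, sd_scale=0.3),
            "total_C": total_c,
            "total_N": total_n,
            "CN": total_c / total_n,
            "Cl": obs(4.0, 0.0, fert),
            "NO2": obs(0.4, -0.12, fert, sd_scale=0.2),
            "NO3": obs(6.0, 1.8, fert),
            "PO4": obs(2.0, 0.7, fert, sd_scale=0.5),
            "SO4": obs(5.0, -1.3, fert),
            "Na": obs(3.0, 0.0, fert),
            "NH4": obs(3.0, 0.9, fert, sd_scale=0.5),
            "K": obs(4.0, 1.2, fert, sd_scale=0.5),
            "Ca": obs(6.0, -1.6, fert),
            "Mg": obs(2.5, 0.0, fert),
        },
        index=idx,
    )
    canopy = obs(25.0, 5.0, plant, sd_scale=2.0)
    leaf_c = obs(47.0, -1.5, plant)
    leaf_n = np.clip(obs(2.2, -0.3, plant, sd_scale=0.3), 0.2, None)
    shoot_c = obs(46.0, -1.2, plant)
    shoot_n = np.clip(obs(1.2, 0.25, plant, sd_scale=0.2), 0.2, None)
    env["canopy_openness"] = canopy
    env["leaf_C"] = leaf_c
    env["leaf_N"] = leaf_n
    env["leaf_CN"] = leaf_c / leaf_n
    env["shoot_C"] = shoot_c
    env["shoot_N"] = shoot_n
    env["shoot_CN"] = shoot_c / shoot_n

    latent = pd.DataFrame(
        {"fertility_score": fert, "phenology_score": plant}, index=idx
    )
    return env, latent


#: Column names of the soil-chemistry block entering the soil PCA.
SOIL_BLOCK = [
    "pH", "total_C", "total_N", "CN", "Cl", "NO2", "NO3", "PO4", "SO4",
    "Na", "NH4", "K", "Ca", "Mg",
]

#: Column names of the plant-trait block entering the plant PCA.
PLANT_BLOCK = [
    "canopy_openness", "leaf_C", "leaf_N", "leaf_CN", "shoot_C", "shoot_N",
    "shoot_CN",
]


def simulate_community(design: pd.DataFrame, params: SimulationParams | None = None,
                       seed=None) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw a genus x sample count table from the NB-regression mixture.

    Each genus g independently draws a component z_g from the mixing
    weights and (optionally) a lognormal abundance offset
    o_g ~ N(0, genus_offset_sd); its counts across samples are then
    NB(mean = exp(beta_{z_g,0} + o_g + beta_{z_g} . x_s), theta_{z_g}),
    independent across samples.  Nonzero offsets spread genera of one
    component over many abundance ranks, producing the left-skewed
    rank-abundance curves typical of genus tables.
    """
    params = params or SimulationParams()
    design = validate_design(design)
    rng = as_rng(seed)
    k = params.k_true
    g = params.n_genera
    if g < k:
        raise InputError("need at least as many genera as components")

    cov = build_covariates(design, params.origin_date)
    xmat = cov.design_matrix().to_numpy()  # S x 5 with leading 1s

    z = rng.choice(k, size=g, p=params.mixing_weights)
    offsets = (
        rng.normal(0.0, params.genus_offset_sd, g)
        if params.genus_offset_sd > 0
        else np.zeros(g)
    )
    eta = params.component_betas[z] @ xmat.T + offsets[:, None]  # G x S
    mu = np.exp(eta)
    theta = params.component_thetas[z][:, None]
    lam = rng.gamma(shape=theta, scale=mu / theta)
    counts = rng.poisson(lam)

    genus_ids = pd.Index([f"g{i:04d}" for i in range(g)], name="genus_id")
    table = pd.DataFrame(counts, index=genus_ids, columns=cov.sample_ids)
    truth = SyntheticTruth(
        labels=pd.Series(z + 1, index=genus_ids, name="component"),
        betas=pd.DataFrame(
            params.component_betas,
            columns=["const", "Sc", "Ss", "Ele", "Dep"],
            index=pd.RangeIndex(1, k + 1, name="component"),
        ),
        thetas=params.component_thetas.copy(),
        weights=params.mixing_weights.copy(),
        offsets=pd.Series(offsets, index=genus_ids, name="offset"),
    )
    return table, truth
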