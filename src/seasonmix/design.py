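"""Sampling design and standardized covariates.

The study design crosses survey sites (elevations), monthly sampling dates
and discrete soil-depth layers.  Every downstream model sees the same four
standardized covariates:

* ``Sc`` — cos(2*pi*d/365), the cosine season score,
* ``Ss`` — sin(2*pi*d/365), the sine season score,
* ``Ele`` — elevation in metres,
* ``Dep`` — soil-depth layer midpoint in centimetres,

where ``d`` counts calendar days from the first sampling date (the origin).
Including both harmonics lets a linear model place its seasonal peak on any
day of the year; ``peak_day`` back-calculates that day from fitted
coefficients.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, InputError, NoSeasonalityError

#: First soil sampling date; day index d = 0.
DEFAULT_ORIGIN = _dt.date(2016, 7, 3)

#: Period of the seasonal harmonics, in days.  Kept at 365 even across
#: leap years: d is an exact calendar-day difference but the harmonic
#: basis always wraps after 365 days.
PERIOD_DAYS = 365.0

#: Canonical depth-layer labels and their numeric midpoints (cm).
DEPTH_MIDPOINTS: dict[str, float] = {
    "0-5": 2.5,
    "5-10": 7.5,
    "10-20": 15.0,
    "20-30": 25.0,
}

DEPTH_LAYERS = tuple(DEPTH_MIDPOINTS)

_MIDPOINT_TO_LAYER = {v: k for k, v in DEPTH_MIDPOINTS.items()}

COVARIATE_NAMES = ("Sc", "Ss", "Ele", "Dep")

#: Default covariate grouping for importance tests: the two harmonics act
#: as one "seasons" block, elevation and depth stand alone.
SEASON_GROUPS: dict[str, list[str]] = {
    "season": ["Sc", "Ss"],
    "Ele": ["Ele"],
    "Dep": ["Dep"],
}


def normalize_depth_layer(layer) -> str:
    """Map a depth-layer alias to its canonical label.

    Accepts "0-5", "0–5 cm" (en dash), "0—5cm", or the numeric
    midpoint (2.5, 7.5, 15, 25).
    """
    if isinstance(layer, (int, float, np.integer, np.floating)) and not isinstance(
        layer, bool
    ):
        mid = float(layer)
        if mid in _MIDPOINT_TO_LAYER:
            return _MIDPOINT_TO_LAYER[mid]
        raise InputError(f"unknown depth midpoint {layer!r}; expected one of "
                         f"{sorted(_MIDPOINT_TO_LAYER)}")
    s = str(layer).strip().replace("–", "-").replace("—", "-")
    s = s.lower().removesuffix("cm").strip()
    s = s.replace(" ", "")
    if s in DEPTH_MIDPOINTS:
        return s
    try:
        return normalize_depth_layer(float(s))
    except (ValueError, InputError):
        pass
    raise InputError(f"unknown depth layer {layer!r}; expected one of {DEPTH_LAYERS}")


def depth_midpoint(layer) -> float:
    """Numeric midpoint (cm) of a depth layer: 0-5 -> 2.5, ..., 20-30 -> 25."""
    return DEPTH_MIDPOINTS[normalize_depth_layer(layer)]


def _as_date(x) -> _dt.date:
    if isinstance(x, _dt.datetime):
        return x.date()
    if isinstance(x, _dt.date):
        return x
    if isinstance(x, str):
        try:
            return _dt.date.fromisoformat(x)
        except ValueError as exc:
            raise InputError(f"malformed date {x!r}: {exc}") from exc
    if isinstance(x, pd.Timestamp):
        return x.date()
    raise InputError(f"cannot interpret {x!r} as a date")


def day_index(date, origin=DEFAULT_ORIGIN) -> int:
    """Exact calendar-day difference ``date - origin`` (negative if earlier)."""
    return (_as_date(date) - _as_date(origin)).days


def seasonal_harmonics(d):
    """Raw harmonic season scores (cos(2*pi*d/365), sin(2*pi*d/365)).

    Vectorized over ``d``.  The pair lies on the unit circle for every d.
    """
    ang = 2.0 * np.pi * np.asarray(d, dtype=float) / PERIOD_DAYS
    return np.cos(ang), np.sin(ang)


def standardize(values):
    """Center and scale to unit variance (sample sd, n-1 denominator).

    Returns ``(z, mean, sd)`` so that ``z * sd + mean`` recovers the input.
    Raises :class:`DegenerateInputError` for constant or too-short input.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise InputError("standardize expects a 1-d vector")
    if v.size < 2:
        raise DegenerateInputError("standardize needs at least 2 values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        raise DegenerateInputError("cannot standardize a constant vector")
    return (v - mean) / sd, mean, sd


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalize a design table.

    Required columns: sample_id, site_id, elevation_m, collection_date,
    depth_layer.  Adds/overwrites ``depth_mid_cm`` from the layer label and
    enforces uniqueness of sample ids and of
    (site_id, collection_date, depth_layer) combinations.
    """
    required = ["sample_id", "site_id", "elevation_m", "collection_date", "depth_layer"]
    missing = [c for c in required if c not in design.columns]
    if missing:
        raise InputError(f"design table missing columns: {missing}")
    out = design.copy()
    out["sample_id"] = out["sample_id"].astype(str)
    if out["sample_id"].duplicated().any():
        dup = out.loc[out["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise InputError(f"duplicate sample_id {dup!r} in design table")
    out["collection_date"] = [_as_date(x) for x in out["collection_date"]]
    out["depth_layer"] = [normalize_depth_layer(x) for x in out["depth_layer"]]
    out["depth_mid_cm"] = [DEPTH_MIDPOINTS[x] for x in out["depth_layer"]]
    key = out[["site_id", "collection_date", "depth_layer"]].astype(str).agg("|".join, axis=1)
    if key.duplicated().any():
        raise InputError(
            "duplicate (site_id, collection_date, depth_layer) combination: "
            f"{key[key.duplicated()].iloc[0]!r}"
        )
    return out


@dataclass
class CovariateMatrix:
    """Standardized covariates (Sc, Ss, Ele, Dep) for a design table.

    ``frame`` holds the z-scored columns indexed by sample_id; ``means`` and
    ``sds`` store the raw per-column moments so the standardization can be
    inverted exactly, and so fitted harmonic coefficients can be mapped back
    to the raw cos/sin basis for phase calculations.
    """

    frame: pd.DataFrame
    means: pd.Series
    sds: pd.Series
    origin_date: _dt.date = field(default=DEFAULT_ORIGIN)

    @property
    def sample_ids(self) -> pd.Index:
        return self.frame.index

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    def design_matrix(self, intercept: bool = True) -> pd.DataFrame:
        """Covariates as a model matrix, optionally with a leading constant."""
        if not intercept:
            return self.frame.copy()
        out = self.frame.copy()
        out.insert(0, "const", 1.0)
        return out

    def unstandardize(self, column: str, z) -> np.ndarray:
        """Invert the z-scoring of one column."""
        return np.asarray(z, dtype=float) * self.sds[column] + self.means[column]


def build_covariates(design: pd.DataFrame, origin_date=DEFAULT_ORIGIN) -> CovariateMatrix:
    """Transform a design table into the standardized covariate matrix.

    Harmonics are evaluated on the day index from ``origin_date``; all four
    columns are then z-scored over all rows of the supplied table.
    """
    design = validate_design(design)
    origin = _as_date(origin_date)
    d = np.array([day_index(x, origin) for x in design["collection_date"]])
    sc_raw, ss_raw = seasonal_harmonics(d)
    raw = pd.DataFrame(
        {
            "Sc": sc_raw,
            "Ss": ss_raw,
            "Ele": design["elevation_m"].astype(float).to_numpy(),
            "Dep": design["depth_mid_cm"].astype(float).to_numpy(),
        },
        index=pd.Index(design["sample_id"], name="sample_id"),
    )
    cols, means, sds = {}, {}, {}
    for name in COVARIATE_NAMES:
        z, mean, sd = standardize(raw[name].to_numpy())
        cols[name], means[name], sds[name] = z, mean, sd
    return CovariateMatrix(
        frame=pd.DataFrame(cols, index=raw.index),
        means=pd.Series(means),
        sds=pd.Series(sds),
        origin_date=origin,
    )


@dataclass
class SeasonalExtrema:
    """Peak and trough of a fitted annual harmonic.

    ``peak_month``/``trough_month`` are the calendar months of the fitted
    extrema themselves; ``peak_sampling_month``/``trough_sampling_month``
    attribute each extremum to the nearest monthly sampling occasion
    (origin date plus whole months), i.e. the month in which the extremum
    would be observed under the monthly design.  The two differ only when
    an extremum falls within a day or two of a month boundary.
    """

    peak_offset_days: float      # days after the origin, in [0, 365)
    trough_offset_days: float
    peak_date: _dt.date
    trough_date: _dt.date
    origin_date: _dt.date = field(default=DEFAULT_ORIGIN)

    @property
    def peak_day_of_year(self) -> int:
        return self.peak_date.timetuple().tm_yday

    @property
    def trough_day_of_year(self) -> int:
        return self.trough_date.timetuple().tm_yday

    @property
    def peak_month(self) -> int:
        return self.peak_date.month

    @property
    def trough_month(self) -> int:
        return self.trough_date.month

    def _nearest_sampling_date(self, date: _dt.date) -> _dt.date:
        origin = pd.Timestamp(self.origin_date)
        candidates = [origin + pd.DateOffset(months=m) for m in range(-1, 14)]
        target = pd.Timestamp(date)
        return min(candidates, key=lambda c: abs((c - target).days)).date()

    @property
    def peak_sampling_month(self) -> int:
        return self._nearest_sampling_date(self.peak_date).month

    @property
    def trough_sampling_month(self) -> int:
        return self._nearest_sampling_date(self.trough_date).month


def peak_day(coef_sc, coef_ss, sd_sc=1.0, sd_ss=1.0, origin=DEFAULT_ORIGIN) -> SeasonalExtrema:
    """Back-calculate the calendar day of the fitted seasonal maximum.

    Coefficients fitted on the *standardized* harmonics are first mapped to
    the raw cos/sin basis (a = coef_sc/sd_sc, b = coef_ss/sd_ss); the fitted
    seasonal term a*cos(wd) + b*sin(wd) then peaks at
    d* = (365/2pi) * atan2(b, a) mod 365 days after the origin, and bottoms
    out exactly half a period (182.5 days) later.
    """
    a = float(coef_sc) / float(sd_sc)
    b = float(coef_ss) / float(sd_ss)
    if a == 0.0 and b == 0.0:
        raise NoSeasonalityError("both harmonic coefficients are zero")
    origin = _as_date(origin)
    d_peak = (PERIOD_DAYS / (2.0 * np.pi)) * np.arctan2(b, a) % PERIOD_DAYS
    d_trough = (d_peak + PERIOD_DAYS / 2.0) % PERIOD_DAYS
    return SeasonalExtrema(
        peak_offset_days=float(d_peak),
        trough_offset_days=float(d_trough),
        peak_date=origin + _dt.timedelta(days=round(float(d_peak))),
        trough_date=origin + _dt.timedelta(days=round(float(d_trough))),
        origin_date=origin,
    )
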