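"""Design grid, harmonic covariates, standardization and phase back-calculation."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seasonmix import (
    build_covariates,
    day_index,
    depth_midpoint,
    peak_day,
    seasonal_harmonics,
    standardize,
)
from seasonmix.design import PERIOD_DAYS, validate_design
from seasonmix.exceptions import DegenerateInputError, InputError, NoSeasonalityError


@pytest.mark.parametrize(
    "date,origin,expected",
    [
        ("2016-07-03", "2016-07-03", 0),
        ("2016-07-04", "2016-07-03", 1),
        ("2017-07-03", "2016-07-03", 365),  # no Feb 29 in this span
        ("2016-07-02", "2016-07-03", -1),
    ],
)
def test_day_index_is_exact_calendar_difference(date, origin, expected):
    assert day_index(date, origin) == expected


def test_day_index_rejects_malformed_dates():
    with pytest.raises(InputError):
        day_index("2016-13-40", "2016-07-03")


def test_seasonal_harmonics_known_values():
    assert seasonal_harmonics(0) == (1.0, 0.0)
    sc, ss = seasonal_harmonics(365)
    assert sc == pytest.approx(1.0, abs=1e-12)
    assert ss == pytest.approx(0.0, abs=1e-12)
    # late-winter day three quarters through the cycle: cosine crosses zero
    sc, ss = seasonal_harmonics(274)
    assert sc == pytest.approx(np.cos(2 * np.pi * 274 / 365), abs=1e-12)
    assert sc == pytest.approx(0.004304, abs=1e-6)
    assert ss == pytest.approx(-0.9999907, abs=1e-6)


@settings(derandomize=True, max_examples=200)
@given(st.integers(min_value=-10_000, max_value=10_000))
def test_harmonics_lie_on_unit_circle_with_period_365(d):
    sc, ss = seasonal_harmonics(d)
    assert sc**2 + ss**2 == pytest.approx(1.0, abs=1e-12)
    sc2, ss2 = seasonal_harmonics(d + 365)
    assert sc2 == pytest.approx(sc, abs=1e-9)
    assert ss2 == pytest.approx(ss, abs=1e-9)


@pytest.mark.parametrize(
    "layer,mid",
    [("0-5", 2.5), ("0–5 cm", 2.5), ("5-10", 7.5), ("10-20", 15.0),
     ("20-30", 25.0), ("20–30 cm", 25.0), (2.5, 2.5), (25, 25.0)],
)
def test_depth_midpoint_mapping_and_aliases(layer, mid):
    assert depth_midpoint(layer) == mid


def test_depth_midpoint_rejects_unknown_layer():
    with pytest.raises(InputError):
        depth_midpoint("30-40")


def test_standardize_hand_case_and_errors():
    z, mean, sd = standardize([1, 2, 3])
    np.testing.assert_allclose(z, [-1, 0, 1])
    assert (mean, sd) == (2.0, 1.0)
    with pytest.raises(DegenerateInputError):
        standardize([5, 5, 5])
    with pytest.raises(DegenerateInputError):
        standardize([1.0])


@settings(derandomize=True, max_examples=100)
@given(
    st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=30).filter(
        lambda v: np.std(v) > 1e-6
    )
)
def test_standardize_roundtrip_and_idempotence(values):
    z, mean, sd = standardize(values)
    np.testing.assert_allclose(z * sd + mean, values, rtol=1e-12, atol=1e-9)
    z2, m2, s2 = standardize(z)
    np.testing.assert_allclose(z2, z, atol=1e-9)
    assert m2 == pytest.approx(0.0, abs=1e-9)
    assert s2 == pytest.approx(1.0, abs=1e-9)


class TestPeakDay:
    def test_pure_cosine_peaks_on_origin_date(self):
        ext = peak_day(1.0, 0.0, origin="2016-07-03")
        assert ext.peak_date == dt.date(2016, 7, 3)
        assert ext.peak_offset_days == 0.0

    def test_peak_and_trough_half_a_period_apart(self):
        ext = peak_day(0.3, -1.2)
        gap = (ext.trough_offset_days - ext.peak_offset_days) % PERIOD_DAYS
        assert gap == pytest.approx(PERIOD_DAYS / 2)

    def test_invariant_to_positive_rescaling_of_coefficients(self):
        a = peak_day(-0.24, -6.61)
        b = peak_day(-0.24 * 7.5, -6.61 * 7.5)
        assert a.peak_offset_days == pytest.approx(b.peak_offset_days)

    def test_both_zero_coefficients_rejected(self):
        with pytest.raises(NoSeasonalityError):
            peak_day(0.0, 0.0)


def test_covariates_standardized_and_invertible(design, cov):
    means = cov.frame.mean()
    sds = cov.frame.std(ddof=1)
    assert means.abs().max() < 1e-9
    np.testing.assert_allclose(sds, 1.0, atol=1e-9)
    # raw harmonics recovered by inverting the z-scores lie on the unit circle
    sc_raw = cov.unstandardize("Sc", cov.frame["Sc"])
    ss_raw = cov.unstandardize("Ss", cov.frame["Ss"])
    np.testing.assert_allclose(sc_raw**2 + ss_raw**2, 1.0, atol=1e-9)
    # elevation inverts to the exact site elevations
    ele = cov.unstandardize("Ele", cov.frame["Ele"])
    assert set(np.round(ele, 1)) == {1831.8, 1334.2, 880.4}


def test_validate_design_rejects_duplicate_combinations(design):
    bad = design.copy()
    bad.loc[1, ["site_id", "collection_date", "depth_layer"]] = bad.loc[
        0, ["site_id", "collection_date", "depth_layer"]
    ]
    with pytest.raises(InputError):
        validate_design(bad)


def test_build_covariates_accepts_origin_shift(design):
    cov185 = build_covariates(design, "2016-01-01")
    # different origin, same standardization contract
    assert cov185.frame["Sc"].mean() == pytest.approx(0.0, abs=1e-9)
    assert cov185.origin_date == dt.date(2016, 1, 1)
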