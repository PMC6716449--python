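"""Synthetic-study generator: design crossing, drivers, count tables."""

import numpy as np
import pandas as pd
import pytest

from seasonmix import (
    SimulationParams,
    fit_linear,
    make_design,
    simulate_community,
    simulate_environment,
)
from seasonmix.exceptions import InputError
from seasonmix.simulate import EnvParams


def test_default_design_is_full_crossing(design):
    assert len(design) == 144  # 3 sites x 12 months x 4 layers
    assert design["site_id"].nunique() == 3
    assert design["collection_date"].nunique() == 12
    assert design["depth_layer"].nunique() == 4


@pytest.mark.parametrize(
    "sites,months,layers,expected",
    [
        ({"a": 100.0}, 1, ("0-5",), 1),
        ({"a": 100.0, "b": 200.0}, 3, ("0-5", "5-10", "10-20", "20-30"), 24),
    ],
)
def test_design_row_count_is_product_of_factors(sites, months, layers, expected):
    params = SimulationParams(
        site_elevations_m=sites, n_months=months, depth_layers=layers
    )
    assert len(make_design(params)) == expected


def test_empty_design_factor_rejected():
    with pytest.raises(InputError):
        make_design(SimulationParams(n_months=0))


def test_invalid_mixture_parameters_rejected():
    with pytest.raises(InputError):
        SimulationParams(mixing_weights=[0.5, 0.6])
    with pytest.raises(InputError):
        SimulationParams(component_thetas=np.array([5.0, -1.0, 5.0]))


def test_counts_are_reproducible_nonnegative_integers(design):
    params = SimulationParams(n_genera=40)
    t1, truth1 = simulate_community(design, params, seed=9)
    t2, truth2 = simulate_community(design, params, seed=9)
    pd.testing.assert_frame_equal(t1, t2)
    pd.testing.assert_series_equal(truth1.labels, truth2.labels)
    assert (t1.to_numpy() >= 0).all()
    assert t1.shape == (40, 144)


def test_poisson_limit_mean_and_dispersion(design):
    # one component at mean 10 with huge theta: index of dispersion -> 1
    params = SimulationParams(
        n_genera=200,
        mixing_weights=[1.0],
        component_betas=np.array([[np.log(10.0), 0, 0, 0, 0]]),
        component_thetas=np.array([1e8]),
    )
    counts, _ = simulate_community(design, params, seed=3)
    vals = counts.to_numpy(dtype=float)
    assert vals.mean() == pytest.approx(10.0, rel=0.02)
    iod = vals.var(axis=1) / vals.mean(axis=1)
    assert np.median(iod) == pytest.approx(1.0, abs=0.1)


def test_component_labels_follow_mixing_weights(design):
    params = SimulationParams(
        n_genera=1000,
        mixing_weights=[0.5, 0.5],
        component_betas=np.array([[3.0, 0, 0.8, 0, 0], [2.0, 0.8, 0, 0, 0]]),
        component_thetas=np.array([5.0, 5.0]),
    )
    _, truth = simulate_community(design, params, seed=11)
    frac = (truth.labels == 1).mean()
    assert abs(frac - 0.5) < 0.05


def test_genus_offsets_produce_left_skewed_rank_abundance(design):
    params = SimulationParams(n_genera=500, genus_offset_sd=1.5)
    counts, _ = simulate_community(design, params, seed=21)
    totals = np.sort(counts.sum(axis=1).to_numpy())[::-1]
    top_decile = totals[: len(totals) // 10].sum()
    assert top_decile / totals.sum() > 0.5


class TestEnvironment:
    def test_zero_noise_soil_temperature_is_exact_sinusoid(self, design):
        env_params = EnvParams(st_noise_sd=0.0)
        params = SimulationParams(env=env_params)
        env, _ = simulate_environment(design, params, seed=0)
        # lowest site: the elevation lapse term vanishes there
        one_site = design[
            (design["site_id"] == "low") & (design["depth_layer"] == "0-5")
        ]
        st = env.loc[one_site["sample_id"], "ST"].to_numpy()
        d = np.array([(x - params.origin_date).days for x in one_site["collection_date"]])
        expected = (
            env_params.st_base
            + env_params.st_amp_sc * np.cos(2 * np.pi * d / 365)
            + env_params.st_amp_ss * np.sin(2 * np.pi * d / 365)
        )
        np.testing.assert_allclose(st, expected, atol=1e-10)

    def test_swc_bounded_between_0_and_100(self, design):
        env, _ = simulate_environment(design, seed=1)
        assert env["SWC"].between(0, 100).all()

    def test_driver_sign_structure_recovered_by_regression(self, design, cov):
        env, _ = simulate_environment(design, seed=2)
        st_fit = fit_linear(env["ST"].loc[cov.sample_ids].to_numpy(), cov)
        assert st_fit.params["Sc"] > 0 and st_fit.params["Ss"] > 0
        assert st_fit.params["Ele"] < 0
        assert st_fit.pvalues["Dep"] > 0.01  # no depth effect built in
        swc_fit = fit_linear(env["SWC"].loc[cov.sample_ids].to_numpy(), cov)
        assert swc_fit.params["Sc"] < 0 < swc_fit.params["Ele"]
        assert swc_fit.params["Dep"] < 0

    def test_cn_ratio_consistent_with_c_and_n(self, design):
        env, _ = simulate_environment(design, seed=3)
        np.testing.assert_allclose(
            env["CN"], env["total_C"] / env["total_N"], rtol=1e-12
        )
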