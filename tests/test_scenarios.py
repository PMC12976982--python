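"""Scenario generator, validation groups, and the projection-error overlay."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

from vdomains.errors import FitError
from vdomains.scenarios import (ScenarioSpec, build_validation_groups,
                                fit_baseline, group_performance_surface,
                                scenario_overlay, simulate_weather)
from vdomains.synthetic import SyntheticConfig, generate_weather
from vdomains.thermal import SEASON_MONTHS, seasonal_mean
from vdomains.transfer import datasets_from_synthetic

from conftest import make_flat_season
from test_transfer import climatology_models


def _noise_free_seasons(n=12, mean=10.0):
    cfg = SyntheticConfig(
        n_locations=2, mean_temp_range=(mean, mean + 2), years_range=(n, n),
        residual_sd=0.0, diurnal_jitter_sd=0.0, seed=1,
    )
    return [s for s in generate_weather(cfg) if s.location == "L00"]


class TestFitBaseline:
    def test_requires_ten_seasons(self):
        with pytest.raises(FitError):
            fit_baseline(_noise_free_seasons(12)[:5])

    def test_noise_free_baseline(self):
        base = fit_baseline(_noise_free_seasons(12))
        assert base.residual_sd == pytest.approx(0.0, abs=0.1)  # leap-day mixing only
        assert base.ar1_coeff == pytest.approx(0.0, abs=0.05)
        assert base.diurnal_range == pytest.approx(8.0, abs=1e-6)

    def test_recovers_generator_monthly_means(self):
        cfg = SyntheticConfig(
            n_locations=2, mean_temp_range=(10.0, 12.0), years_range=(30, 30),
            seed=13,
        )
        seasons = [s for s in generate_weather(cfg) if s.location == "L00"]
        clean = fit_baseline(_noise_free_seasons(12))
        noisy = fit_baseline(seasons)
        for m in SEASON_MONTHS:
            assert noisy.monthly_means[m] == pytest.approx(
                clean.monthly_means[m], abs=0.3
            )

    def test_invariant_to_season_order(self):
        seasons = _noise_free_seasons(12)
        a = fit_baseline(seasons)
        b = fit_baseline(list(reversed(seasons)))
        assert a.monthly_means == b.monthly_means
        assert a.residual_sd == pytest.approx(b.residual_sd, rel=1e-12)

    def test_reference_window_filters_years(self):
        seasons = _noise_free_seasons(12)
        years = sorted(s.year for s in seasons)
        base = fit_baseline(seasons, reference_window=(years[2], years[-1]))
        assert base.n_seasons == len(years) - 2


class TestSimulateWeather:
    def test_zero_delta_zero_sd_reproduces_baseline(self):
        base = fit_baseline(_noise_free_seasons(12))
        spec = ScenarioSpec.uniform("SSP1.26", 2050, 0.0, n_simulations=5, seed=0)
        seasons, dist = simulate_weather(base, spec)
        ref = np.mean(
            [seasonal_mean(s).seasonal_mean for s in _noise_free_seasons(12)]
        )
        # monthly-mean climatology reproduces the seasonal mean closely
        np.testing.assert_allclose(dist.seasonal_means, ref, atol=0.15)
        assert len(seasons) == 5

    def test_uniform_delta_shifts_mean(self):
        cfg = SyntheticConfig(
            n_locations=2, mean_temp_range=(10.0, 12.0), years_range=(30, 30), seed=2
        )
        seasons = [s for s in generate_weather(cfg) if s.location == "L00"]
        base = fit_baseline(seasons)
        zero = simulate_weather(
            base, ScenarioSpec.uniform("x", 2050, 0.0, 100, seed=5)
        )[1]
        plus2 = simulate_weather(
            base, ScenarioSpec.uniform("x", 2050, 2.0, 100, seed=5)
        )[1]
        shift = plus2.seasonal_means.mean() - zero.seasonal_means.mean()
        assert shift == pytest.approx(2.0, abs=0.1)

    def test_same_seed_identical_different_seed_same_distribution(self):
        cfg = SyntheticConfig(
            n_locations=2, mean_temp_range=(10.0, 12.0), years_range=(30, 30), seed=2
        )
        base = fit_baseline([s for s in generate_weather(cfg) if s.location == "L00"])
        a = simulate_weather(base, ScenarioSpec.uniform("x", 2050, 1.0, 1000, seed=1))[1]
        a2 = simulate_weather(base, ScenarioSpec.uniform("x", 2050, 1.0, 1000, seed=1))[1]
        b = simulate_weather(base, ScenarioSpec.uniform("x", 2050, 1.0, 1000, seed=2))[1]
        np.testing.assert_array_equal(a.seasonal_means, a2.seasonal_means)
        assert not np.array_equal(a.seasonal_means, b.seasonal_means)
        assert ks_2samp(a.seasonal_means, b.seasonal_means).pvalue > 0.01

    def test_iqr_within_simulated_range(self):
        cfg = SyntheticConfig(
            n_locations=2, mean_temp_range=(10.0, 12.0), years_range=(30, 30), seed=2
        )
        base = fit_baseline([s for s in generate_weather(cfg) if s.location == "L00"])
        dist = simulate_weather(base, ScenarioSpec.uniform("x", 2050, 1.0, 100, seed=3))[1]
        lo, hi = dist.iqr
        assert dist.seasonal_means.min() <= lo <= dist.median <= hi <= dist.seasonal_means.max()


class TestValidationGroups:
    def test_paper_binning_yields_22_groups(self, tiny_dataset):
        datasets = datasets_from_synthetic(tiny_dataset)
        groups = build_validation_groups(datasets, 0.5, 30, (7.0, 18.0), seed=0)
        assert len(groups) == 22
        assert all(g.n_seasons <= 30 for g in groups)

    def test_members_lie_in_their_bin(self, tiny_dataset):
        datasets = datasets_from_synthetic(tiny_dataset)
        groups = build_validation_groups(datasets, 0.5, 30, (7.0, 13.0), seed=0)
        for g in groups:
            if not g.is_empty:
                assert np.all(g.member_means >= g.bin_lo)
                assert np.all(g.member_means < g.bin_hi)

    def test_half_open_boundary(self):
        datasets = {}
        # one season with mean exactly 7.5 goes to the second bin
        season = make_flat_season(tmin=7.5, tmax=7.5)
        from vdomains.transfer import LocationDataset

        datasets["X"] = LocationDataset("X", 35.0, [season], np.array([90.0]))
        groups = build_validation_groups(datasets, 0.5, 30, (7.0, 8.0), seed=0)
        assert groups[0].is_empty
        assert groups[1].n_seasons == 1

    def test_cap_enforced_and_reproducible(self, mid_gradient_dataset):
        datasets = datasets_from_synthetic(mid_gradient_dataset)
        a = build_validation_groups(datasets, 2.0, 5, (7.0, 15.0), seed=4)
        b = build_validation_groups(datasets, 2.0, 5, (7.0, 15.0), seed=4)
        assert any(g.n_seasons == 5 for g in a)
        assert [g.members for g in a] == [g.members for g in b]


class TestOverlay:
    @pytest.fixture(scope="class")
    def overlay_inputs(self, mid_gradient_dataset):
        datasets = datasets_from_synthetic(mid_gradient_dataset)
        models = climatology_models(datasets)
        means = [ds.t_mean for ds in datasets.values()]
        grange = (np.floor(min(means)), np.ceil(max(means)))
        groups = build_validation_groups(datasets, 0.5, 30, grange, seed=0)
        return datasets, models, groups

    def test_identity_scenario_recovers_local_performance(self, overlay_inputs):
        """With zero deltas and no weather noise, the expected error at a
        location approaches its own-bin performance."""
        datasets, models, groups = overlay_inputs
        loc, ds = list(datasets.items())[2]  # mid-gradient location
        base = fit_baseline(ds.seasons)
        base.residual_sd = 0.0
        spec = ScenarioSpec.uniform("SSP1.26", 2050, 0.0, n_simulations=10, seed=0)
        _, dist = simulate_weather(base, spec)
        surf = group_performance_surface(models, groups, resolution=0.1)
        table = scenario_overlay(models, groups, [dist], surface=surf)
        row = table.iloc[0]
        own = surf.predict([models[loc].t_calib], [ds.t_mean])[0]
        assert row["median_rmse"] == pytest.approx(own, abs=1.0)
        assert row["frac_beyond_range"] == 0.0

    def test_warmer_scenarios_never_reduce_flagged_fraction(self, overlay_inputs):
        datasets, models, groups = overlay_inputs
        eligible = [l for l, d in datasets.items() if d.n_seasons >= 10]
        loc = eligible[-1]  # warmest location with enough baseline seasons
        ds = datasets[loc]
        base = fit_baseline(ds.seasons)
        fracs = []
        for delta in (0.0, 2.0, 4.0, 8.0):
            spec = ScenarioSpec.uniform("x", 2050, delta, n_simulations=50, seed=1)
            _, dist = simulate_weather(base, spec)
            table = scenario_overlay(models, groups, [dist], resolution=0.2)
            fracs.append(table["frac_beyond_range"].iloc[0])
        assert all(b >= a - 1e-12 for a, b in zip(fracs, fracs[1:]))
        assert fracs[-1] == 1.0  # +8 °C pushes everything beyond the data

    def test_flagged_fraction_counts_out_of_range_sims(self, overlay_inputs):
        datasets, models, groups = overlay_inputs
        eligible = [l for l, d in datasets.items() if d.n_seasons >= 10]
        ds = datasets[eligible[-1]]
        base = fit_baseline(ds.seasons)
        spec = ScenarioSpec.uniform("x", 2050, 3.0, n_simulations=40, seed=2)
        _, dist = simulate_weather(base, spec)
        table = scenario_overlay(models, groups, [dist], resolution=0.2)
        centers = [g.t_mean for g in groups if not g.is_empty]
        expected = np.mean(
            (dist.seasonal_means < min(centers)) | (dist.seasonal_means > max(centers))
        )
        assert table["frac_beyond_range"].iloc[0] == pytest.approx(expected)
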