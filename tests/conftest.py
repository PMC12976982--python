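"""Shared fixtures: small synthetic datasets reused across test modules."""

import numpy as np
import pytest

from vdomains.synthetic import SyntheticConfig, generate_dataset
from vdomains.thermal import DailySeason, season_dates


def make_flat_season(
    tmin=8.0, tmax=12.0, year=2000, location="X", latitude=35.0
) -> DailySeason:
    """A season with constant daily extremes; the simplest valid input."""
    dates = season_dates(year)
    n = len(dates)
    return DailySeason(
        location, latitude, year, dates,
        np.full(n, float(tmin)), np.full(n, float(tmax)),
    )


@pytest.fixture(scope="session")
def flat_season():
    return make_flat_season()


@pytest.fixture(scope="session")
def tiny_dataset():
    """3 locations x 8 seasons around 8-12 °C; fast to generate."""
    cfg = SyntheticConfig(
        n_locations=3, mean_temp_range=(8.0, 12.0), years_range=(8, 8), seed=3
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def demo_pipeline(tmp_path_factory):
    """Full workflow on the default demo gradient with a warm failure
    margin (8 locations, 6-17 °C, 20 seasons each); shared across the
    end-to-end tests because calibration dominates its run time."""
    from vdomains.pipeline import RunConfig, run_pipeline

    out = tmp_path_factory.mktemp("demo_run")
    config = RunConfig(
        out_dir=str(out),
        n_locations=8,
        mean_temp_range=(6.0, 17.0),
        years_range=(20, 20),
        obs_noise_sd=1.5,
        budget=1500,
        resolution=0.1,
        seed=1,
    )
    return run_pipeline(config)


@pytest.fixture(scope="session")
def mid_gradient_dataset():
    """5 locations x 12 seasons spanning 7-15 °C, noise-free observations."""
    cfg = SyntheticConfig(
        n_locations=5,
        mean_temp_range=(7.0, 15.0),
        years_range=(12, 12),
        obs_noise_sd=0.0,
        seed=11,
    )
    return generate_dataset(cfg)
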