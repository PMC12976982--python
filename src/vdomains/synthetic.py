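"""Synthetic multi-location weather and ground-truth bloom observations.

The generator emulates the statistical structure of long-term cherry
phenology records along a coastal temperature gradient: tens of locations
whose September-May mean temperatures increase smoothly from cold-winter
(~5 °C) to warm-winter (~15-16 °C) climates, several decades of seasons
per location, daily tmin/tmax with an annual cycle and day-to-day
autocorrelation, and bloom dates produced by a known process model plus
rounded observation noise.  Because the generating parameters are known,
every downstream stage (calibration, transfer, kriging, scenarios) can be
tested for recovery against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, GenerationError
from .phenoflex import BloomStatus, PhenoFlexParams, predict_bloom
from .thermal import DailySeason, season_dates, seasons_to_frame, to_hourly

#: Ground-truth process parameters used by default.  Chosen so that bloom
#: falls in March-April at a ~10 °C-seasonal-mean location and chill
#: accumulation fails for most seasons once seasonal means exceed ~18 °C.
DEFAULT_TRUTH_PARAMS = PhenoFlexParams(
    yc=48.0,
    zc=300.0,
    s1=0.5,
    Tu=25.0,
    E0=3372.8,
    E1=9900.3,
    A0=6319.5,
    A1=5.939917e13,
    Tf=4.0,
    Tc=36.0,
    Tb=4.0,
    slope=1.6,
)

#: Day of the annual temperature minimum (late January).
COLDEST_DOY = 25

#: Latitudes assigned across the gradient, cold to warm (degrees north).
LATITUDE_COLD, LATITUDE_WARM = 43.0, 31.5


@dataclass(frozen=True)
class SyntheticConfig:
    """Settings of the synthetic gradient.

    Defaults mirror the emulation target: location seasonal means spanning
    5-16 °C, 27-64 seasons per location, an ~11 °C annual half-range and
    an 8 °C mean diurnal range with AR(1) day-to-day residuals.
    """

    n_locations: int = 12
    mean_temp_range: tuple[float, float] = (5.0, 16.0)
    years_range: tuple[int, int] = (27, 64)
    seasonal_amplitude: float = 11.0
    diurnal_range: float = 8.0
    ar1_coeff: float = 0.7
    residual_sd: float = 2.5
    diurnal_jitter_sd: float = 0.5
    obs_noise_sd: float = 1.5
    truth_params: PhenoFlexParams = DEFAULT_TRUTH_PARAMS
    last_year: int = 2020
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_locations < 2:
            raise ConfigurationError("need at least 2 locations")
        if not (0.0 <= self.ar1_coeff < 1.0):
            raise ConfigurationError("ar1_coeff must be in [0, 1)")
        if self.residual_sd < 0 or self.obs_noise_sd < 0 or self.diurnal_jitter_sd < 0:
            raise ConfigurationError("noise scales must be non-negative")
        lo, hi = self.mean_temp_range
        if not lo < hi:
            raise ConfigurationError("mean_temp_range lower bound must be < upper")
        ylo, yhi = self.years_range
        if not (1 <= ylo <= yhi):
            raise ConfigurationError("years_range must be ordered and positive")

    @property
    def location_means(self) -> np.ndarray:
        """Target Sep-May mean per location, monotone in location index."""
        lo, hi = self.mean_temp_range
        return np.linspace(lo, hi, self.n_locations)

    @property
    def location_ids(self) -> list[str]:
        return [f"L{i:02d}" for i in range(self.n_locations)]

    @property
    def location_latitudes(self) -> np.ndarray:
        lo, hi = self.mean_temp_range
        frac = (self.location_means - lo) / (hi - lo)
        return LATITUDE_COLD + frac * (LATITUDE_WARM - LATITUDE_COLD)


@dataclass
class SyntheticDataset:
    """Generated weather, observed phenology, and the generating truth."""

    config: SyntheticConfig
    weather: list[DailySeason]
    phenology: pd.DataFrame           # location, year, bloom_doy
    truth: pd.DataFrame               # location, year, true_doy
    failures: pd.DataFrame            # location, n_seasons, n_failed

    def seasons_for(self, location: str) -> list[DailySeason]:
        return [s for s in self.weather if s.location == location]

    def observed_for(self, location: str) -> pd.DataFrame:
        return self.phenology[self.phenology["location"] == location]

    def write(self, directory) -> None:
        """Dump weather/phenology CSVs and a truth YAML into ``directory``."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        seasons_to_frame(self.weather).to_csv(d / "weather.csv", index=False)
        self.phenology.to_csv(d / "phenology.csv", index=False)
        truth = {
            "seed": self.config.seed,
            "obs_noise_sd": self.config.obs_noise_sd,
            "params": self.config.truth_params.to_dict(),
        }
        with open(d / "truth.yaml", "w") as fh:
            yaml.safe_dump(truth, fh)
        self.truth.to_csv(d / "true_bloom.csv", index=False)


# ---------------------------------------------------------------------------
# Weather generation
# ---------------------------------------------------------------------------

def _annual_cycle(dates: np.ndarray, bloom_year: int, amplitude: float) -> np.ndarray:
    """Annual cosine with its minimum on day ``COLDEST_DOY`` (late January)."""
    coldest = np.datetime64(f"{bloom_year}-01-01", "D") + (COLDEST_DOY - 1)
    delta = (dates - coldest).astype(int)
    return -amplitude * np.cos(2.0 * np.pi * delta / 365.25)


def _location_offset(target_mean: float, amplitude: float) -> float:
    """Constant making the Sep-May mean of the annual cycle hit the target."""
    ref = season_dates(2001)  # non-leap reference season
    return target_mean - float(np.mean(_annual_cycle(ref, 2001, amplitude)))


def generate_weather(config: SyntheticConfig) -> list[DailySeason]:
    """Daily tmin/tmax for every location-season of the configured gradient.

    Each location draws from its own random stream derived from the master
    seed, so regenerating with more locations leaves existing ones
    untouched.  tmean = offset + annual cosine + AR(1) residual;
    tmin/tmax sit half the diurnal range below/above tmean plus
    independent jitter.
    """
    seasons: list[DailySeason] = []
    means = config.location_means
    lats = config.location_latitudes
    for li, loc in enumerate(config.location_ids):
        rng = np.random.default_rng((config.seed, li))
        n_years = int(rng.integers(config.years_range[0], config.years_range[1] + 1))
        offset = _location_offset(means[li], config.seasonal_amplitude)
        for year in range(config.last_year - n_years + 1, config.last_year + 1):
            dates = season_dates(year)
            n = len(dates)
            tmean = offset + _annual_cycle(dates, year, config.seasonal_amplitude)
            if config.residual_sd > 0:
                innov_sd = config.residual_sd * np.sqrt(1.0 - config.ar1_coeff**2)
                resid = np.empty(n)
                resid[0] = rng.normal(0.0, config.residual_sd)
                shocks = rng.normal(0.0, innov_sd, n - 1)
                for t in range(1, n):
                    resid[t] = config.ar1_coeff * resid[t - 1] + shocks[t - 1]
                tmean = tmean + resid
            half = config.diurnal_range / 2.0
            jit = (
                rng.normal(0.0, config.diurnal_jitter_sd, (2, n))
                if config.diurnal_jitter_sd > 0
                else np.zeros((2, n))
            )
            tmin = tmean - half + jit[0]
            tmax = tmean + half + jit[1]
            lo = np.minimum(tmin, tmax)
            hi = np.maximum(tmin, tmax)
            seasons.append(DailySeason(loc, float(lats[li]), year, dates, lo, hi))
    return seasons


# ---------------------------------------------------------------------------
# Phenology generation
# ---------------------------------------------------------------------------

def generate_phenology(
    weather: list[DailySeason],
    truth_params: PhenoFlexParams,
    obs_noise_sd: float,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run the truth model over every season and add observation noise.

    Returns ``(phenology, truth, failures)``: observed records
    (location, year, bloom_doy), the noise-free truth (location, year,
    true_doy), and per-location failure counts.  Seasons where the truth
    model never reaches its heat requirement are dropped from both tables
    and tallied in ``failures``.  Raises :class:`GenerationError` when
    more than half of all seasons fail (an unviable gradient).
    """
    locations = sorted({s.location for s in weather})
    loc_index = {loc: i for i, loc in enumerate(locations)}
    obs_rows, truth_rows = [], []
    n_seasons = {loc: 0 for loc in locations}
    n_failed = {loc: 0 for loc in locations}
    rngs = {loc: np.random.default_rng((seed, loc_index[loc], 1)) for loc in locations}
    for s in weather:
        n_seasons[s.location] += 1
        pred = predict_bloom(to_hourly(s), truth_params)
        if pred.status is BloomStatus.FAILURE:
            n_failed[s.location] += 1
            continue
        true_doy = int(pred.bloom_doy)
        noise = rngs[s.location].normal(0.0, obs_noise_sd) if obs_noise_sd > 0 else 0.0
        observed = int(np.clip(true_doy + round(noise), 1, 200))
        obs_rows.append((s.location, s.year, observed))
        truth_rows.append((s.location, s.year, true_doy))
    total = sum(n_seasons.values())
    failed = sum(n_failed.values())
    if total and failed > 0.5 * total:
        raise GenerationError(
            f"truth model failed on {failed}/{total} seasons; gradient unviable"
        )
    phenology = pd.DataFrame(obs_rows, columns=["location", "year", "bloom_doy"])
    truth = pd.DataFrame(truth_rows, columns=["location", "year", "true_doy"])
    failures = pd.DataFrame(
        {
            "location": locations,
            "n_seasons": [n_seasons[l] for l in locations],
            "n_failed": [n_failed[l] for l in locations],
        }
    )
    return phenology, truth, failures


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Full synthetic dataset: weather plus ground-truth phenology."""
    weather = generate_weather(config)
    phenology, truth, failures = generate_phenology(
        weather, config.truth_params, config.obs_noise_sd, config.seed
    )
    return SyntheticDataset(config, weather, phenology, truth, failures)
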