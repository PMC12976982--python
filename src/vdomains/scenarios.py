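"""Future-climate overlay: simplified weather generation, thermally
binned validation groups, and expected projection errors.

To ask "how wrong will a bloom model be under a future climate?", the
historical seasons of *all* locations are pooled and binned by seasonal
mean temperature into location-independent validation groups.  Every
calibrated model is evaluated against every group, and kriging over
(calibration temperature, group temperature) yields a performance surface
indexed by conditions rather than locations.  A stochastic AR(1) weather
generator, fitted per location to a reference period and shifted by
scenario-specific monthly temperature deltas (one delta set per SSP and
horizon year), then produces distributions of future seasonal means;
reading the surface at those simulated means gives the distribution of
expected RMSE for each location under each scenario.  Simulated seasons
warmer than any validation group are flagged as beyond the range of the
available validation data.
"""

from __future__ import annotations

import zlib

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibrate import FAILURE_PENALTY
from .errors import FitError, InputError
from .surface import PerformanceSurface, krige
from .thermal import SEASON_MONTHS, DailySeason, season_dates, seasonal_mean
from .transfer import BloomModel, LocationDataset, evaluate_pair

#: Illustrative seasonal warming (°C vs. the ~2000 reference) per SSP and
#: horizon year, applied uniformly across months unless overridden.
DEFAULT_SCENARIO_DELTAS: dict[tuple[str, int], float] = {
    ("SSP1.26", 2050): 1.0,
    ("SSP2.45", 2050): 1.4,
    ("SSP5.85", 2050): 2.0,
    ("SSP1.26", 2085): 1.2,
    ("SSP2.45", 2085): 2.4,
    ("SSP5.85", 2085): 4.3,
}

DEFAULT_GROUP_RANGE = (7.0, 18.0)  # °C
DEFAULT_BIN_WIDTH = 0.5            # °C
DEFAULT_GROUP_CAP = 30             # seasons per group


@dataclass(frozen=True)
class ScenarioSpec:
    """One SSP x horizon-year scenario."""

    ssp: str
    horizon_year: int
    monthly_deltas: Mapping[int, float]  # calendar month -> °C shift
    n_simulations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_simulations < 1:
            raise InputError("n_simulations must be >= 1")
        if not all(np.isfinite(list(self.monthly_deltas.values()))):
            raise InputError("scenario deltas must be finite")

    @classmethod
    def uniform(cls, ssp: str, horizon_year: int, delta: float,
                n_simulations: int = 100, seed: int = 0) -> "ScenarioSpec":
        return cls(ssp, horizon_year, {m: delta for m in SEASON_MONTHS},
                   n_simulations, seed)


def default_scenarios(n_simulations: int = 100, seed: int = 0) -> list[ScenarioSpec]:
    return [
        ScenarioSpec.uniform(ssp, year, d, n_simulations, seed)
        for (ssp, year), d in DEFAULT_SCENARIO_DELTAS.items()
    ]


# ---------------------------------------------------------------------------
# Baseline fit and weather simulation
# ---------------------------------------------------------------------------

def _calendar_keys(dates: np.ndarray) -> list[tuple[int, int]]:
    idx = pd.DatetimeIndex(dates)
    return list(zip(idx.month, idx.day))


@dataclass
class BaselineParams:
    """Per-location generator parameters estimated from baseline seasons."""

    location: str
    latitude: float
    day_climatology: dict[tuple[int, int], float]  # (month, day) -> °C
    monthly_means: dict[int, float]                # calendar month -> °C
    residual_sd: float
    ar1_coeff: float
    diurnal_range: float
    n_seasons: int


def fit_baseline(
    seasons: Sequence[DailySeason],
    reference_window: tuple[int, int] | None = None,
) -> BaselineParams:
    """Estimate the daily climatology, residual sd and AR(1) coefficient.

    The climatology is the across-season mean of daily (tmin+tmax)/2 per
    calendar day; residuals are deviations from it, so with noise-free
    input the residual sd is ~0 and the AR coefficient is reported as 0.
    ``reference_window`` restricts to bloom years in [lo, hi].  Requires
    at least 10 seasons.
    """
    if reference_window is not None:
        lo, hi = reference_window
        seasons = [s for s in seasons if lo <= s.year <= hi]
    if len(seasons) < 10:
        raise FitError("need at least 10 baseline seasons")
    sums: dict[tuple[int, int], float] = {}
    counts: dict[tuple[int, int], int] = {}
    for s in seasons:
        tmean = (s.tmin + s.tmax) / 2.0
        for key, t in zip(_calendar_keys(s.dates), tmean):
            sums[key] = sums.get(key, 0.0) + float(t)
            counts[key] = counts.get(key, 0) + 1
    clim = {k: sums[k] / counts[k] for k in sums}
    monthly = {
        m: float(np.mean([v for (mm, _), v in clim.items() if mm == m]))
        for m in SEASON_MONTHS
    }

    ac_num = ac_den = 0.0
    resid_parts = []
    for s in seasons:
        tmean = (s.tmin + s.tmax) / 2.0
        base = np.array([clim[k] for k in _calendar_keys(s.dates)])
        r = tmean - base
        resid_parts.append(r)
        ac_num += float(np.sum(r[1:] * r[:-1]))
        ac_den += float(np.sum(r[:-1] ** 2))
    resid = np.concatenate(resid_parts)
    sd = float(resid.std())
    # the AR coefficient is undefined for (near-)noise-free residuals;
    # report 0 rather than a spurious near-unit estimate
    if sd < 0.1 or ac_den <= 1e-12:
        ar1 = 0.0
    else:
        ar1 = float(np.clip(ac_num / ac_den, 0.0, 0.999))
    dr = float(np.mean(np.concatenate([s.tmax - s.tmin for s in seasons])))
    return BaselineParams(
        location=seasons[0].location,
        latitude=seasons[0].latitude,
        day_climatology=clim,
        monthly_means=monthly,
        residual_sd=sd,
        ar1_coeff=ar1,
        diurnal_range=dr,
        n_seasons=len(seasons),
    )


@dataclass
class ScenarioDistribution:
    """Simulated seasonal-mean distribution for one location x scenario."""

    location: str
    spec: ScenarioSpec
    seasonal_means: np.ndarray

    @property
    def median(self) -> float:
        return float(np.median(self.seasonal_means))

    @property
    def iqr(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.seasonal_means, [25, 75])
        return float(lo), float(hi)


def simulate_weather(
    baseline: BaselineParams, spec: ScenarioSpec
) -> tuple[list[DailySeason], ScenarioDistribution]:
    """Generate ``n_simulations`` synthetic seasons under a scenario.

    Daily mean = baseline monthly mean + scenario delta + AR(1) residual;
    tmin/tmax sit half the baseline diurnal range below/above.  The
    stream is seeded from (spec.seed, location hash), so repeated calls
    are identical.
    """
    loc_key = zlib.crc32(baseline.location.encode())  # stable across runs
    rng = np.random.default_rng((spec.seed, loc_key, spec.horizon_year))
    dates = season_dates(spec.horizon_year)
    months = dates.astype("datetime64[M]").astype(int) % 12 + 1
    clim = baseline.day_climatology
    feb28 = clim.get((2, 28), np.mean(list(clim.values())))
    base = np.array(
        [
            clim.get(key, feb28) + spec.monthly_deltas.get(m, 0.0)
            for key, m in zip(_calendar_keys(dates), months)
        ]
    )
    half = baseline.diurnal_range / 2.0
    out, means = [], np.empty(spec.n_simulations)
    n = len(dates)
    phi, sd = baseline.ar1_coeff, baseline.residual_sd
    for k in range(spec.n_simulations):
        if sd > 0:
            innov = sd * np.sqrt(1.0 - phi**2)
            r = np.empty(n)
            r[0] = rng.normal(0.0, sd)
            shocks = rng.normal(0.0, innov, n - 1)
            for t in range(1, n):
                r[t] = phi * r[t - 1] + shocks[t - 1]
        else:
            r = np.zeros(n)
        tmean = base + r
        season = DailySeason(
            f"{baseline.location}-sim{k:03d}",
            baseline.latitude,
            spec.horizon_year,
            dates,
            tmean - half,
            tmean + half,
        )
        out.append(season)
        means[k] = seasonal_mean(season).seasonal_mean
    return out, ScenarioDistribution(baseline.location, spec, means)


# ---------------------------------------------------------------------------
# Location-independent validation groups
# ---------------------------------------------------------------------------

@dataclass
class ValidationGroup:
    """Thermally similar seasons pooled across locations."""

    bin_lo: float
    bin_hi: float
    hourly: list = field(default_factory=list)
    features: list = field(default_factory=list)
    observed: np.ndarray = field(default_factory=lambda: np.empty(0))
    members: list[tuple[str, int]] = field(default_factory=list)
    member_means: np.ndarray = field(default_factory=lambda: np.empty(0))

    # evaluate_pair interface
    @property
    def location(self) -> str:
        return f"bin[{self.bin_lo:.1f},{self.bin_hi:.1f})"

    @property
    def t_mean(self) -> float:
        return 0.5 * (self.bin_lo + self.bin_hi)

    @property
    def n_seasons(self) -> int:
        return len(self.members)

    @property
    def is_empty(self) -> bool:
        return not self.members


def build_validation_groups(
    datasets: Mapping[str, LocationDataset],
    bin_width: float = DEFAULT_BIN_WIDTH,
    cap: int = DEFAULT_GROUP_CAP,
    t_range: tuple[float, float] = DEFAULT_GROUP_RANGE,
    seed: int = 0,
) -> list[ValidationGroup]:
    """Bin all seasons of all locations into half-open [lo, lo+width) groups.

    Per bin, up to ``cap`` seasons are drawn uniformly at random without
    replacement (seeded).  Empty bins are retained as empty groups so the
    group count is a function of the range alone.
    """
    lo, hi = t_range
    edges = np.arange(lo, hi - 1e-9, bin_width)
    pool = []  # (mean, location, index)
    for loc, ds in datasets.items():
        for i, m in enumerate(ds.seasonal_means):
            pool.append((float(m), loc, i))
    rng = np.random.default_rng(seed)
    groups = []
    for blo in edges:
        bhi = blo + bin_width
        members = [(m, loc, i) for (m, loc, i) in pool if blo <= m < bhi]
        if len(members) > cap:
            pick = rng.choice(len(members), size=cap, replace=False)
            members = [members[j] for j in sorted(pick)]
        g = ValidationGroup(float(blo), float(bhi))
        for m, loc, i in members:
            ds = datasets[loc]
            g.hourly.append(ds.hourly[i])
            g.features.append(ds.features[i])
            g.members.append((loc, ds.seasons[i].year))
        g.observed = np.array(
            [datasets[loc].observed[i] for (m, loc, i) in members], dtype=float
        )
        g.member_means = np.array([m for (m, loc, i) in members])
        groups.append(g)
    return groups


# ---------------------------------------------------------------------------
# Overlay
# ---------------------------------------------------------------------------

def group_performance_surface(
    models: Mapping[str, BloomModel],
    groups: Sequence[ValidationGroup],
    penalty: float = FAILURE_PENALTY,
    resolution: float = 0.05,
) -> PerformanceSurface:
    """Krige model-vs-group RMSE over (calibration T, group bin center)."""
    x, y, v = [], [], []
    for model in models.values():
        for g in groups:
            if g.is_empty:
                continue
            cell = evaluate_pair(model, g, penalty)
            x.append(cell.t_calib)
            y.append(g.t_mean)
            v.append(cell.rmse)
    return krige(np.array(x), np.array(y), np.array(v), resolution=resolution)


def scenario_overlay(
    models: Mapping[str, BloomModel],
    groups: Sequence[ValidationGroup],
    distributions: Sequence[ScenarioDistribution],
    penalty: float = FAILURE_PENALTY,
    resolution: float = 0.05,
    surface: PerformanceSurface | None = None,
) -> pd.DataFrame:
    """Expected projection error per location x scenario.

    For each model and each matching scenario distribution, the kriged
    group surface is read at (model calibration T, simulated seasonal
    mean) for every simulation; the table reports the median and IQR of
    those expected RMSE values and the fraction of simulations whose
    means fall outside the validation-group range ("beyond validation
    data").
    """
    surf = surface or group_performance_surface(models, groups, penalty, resolution)
    centers = [g.t_mean for g in groups if not g.is_empty]
    v_lo, v_hi = min(centers), max(centers)
    rows = []
    for dist in distributions:
        model = models.get(dist.location)
        if model is None:
            continue
        sims = dist.seasonal_means
        inside = (sims >= v_lo) & (sims <= v_hi)
        frac_beyond = float(1.0 - inside.mean())
        if inside.any():
            rmse = surf.predict(
                np.full(inside.sum(), float(model.t_calib)), sims[inside]
            )
            med = float(np.median(rmse))
            q1, q3 = np.percentile(rmse, [25, 75])
        else:
            med, q1, q3 = np.nan, np.nan, np.nan
        rows.append(
            {
                "location": dist.location,
                "ssp": dist.spec.ssp,
                "horizon_year": dist.spec.horizon_year,
                "t_calib": float(model.t_calib),
                "median_rmse": med,
                "iqr_lo": float(q1) if np.isfinite(q1) else np.nan,
                "iqr_hi": float(q3) if np.isfinite(q3) else np.nan,
                "frac_beyond_range": frac_beyond,
            }
        )
    return pd.DataFrame(rows)
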