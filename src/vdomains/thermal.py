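"""Dormancy-season assembly and temperature preprocessing.

A *season* is the stretch of daily weather relevant for predicting one
spring bloom: September 1 of the previous calendar year through May 31 of
the bloom year.  This module builds those season windows from daily
tmin/tmax records, filters out seasons with too many missing days, fills
the remaining gaps, interpolates daily extremes to hourly temperatures
(half-sine day course, logarithmic night decay, sunrise/sunset from solar
declination), and computes seasonal summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, UnfillableSeasonError, UnsupportedLatitudeError

#: Months belonging to the dormancy season, in season order (Sep .. May).
SEASON_MONTHS: tuple[int, ...] = (9, 10, 11, 12, 1, 2, 3, 4, 5)

#: Latitude limit beyond which every day has a sunrise and a sunset.
POLAR_LATITUDE = 66.6


def season_dates(year: int) -> np.ndarray:
    """Daily calendar from Sep 1 of ``year - 1`` to May 31 of ``year``."""
    start = np.datetime64(f"{year - 1}-09-01", "D")
    stop = np.datetime64(f"{year}-06-01", "D")
    return np.arange(start, stop)


def day_of_year(dates: np.ndarray, bloom_year: int) -> np.ndarray:
    """Integer day-of-year counted from Jan 1 of the bloom year (1-based).

    Dates in the preceding autumn map to zero or negative values, so the
    returned axis is monotone across the New Year boundary.
    """
    jan1 = np.datetime64(f"{bloom_year}-01-01", "D")
    return (np.asarray(dates, dtype="datetime64[D]") - jan1).astype(int) + 1


@dataclass
class DailySeason:
    """One location-year of daily weather on the fixed season window.

    ``tmin``/``tmax`` are °C with NaN marking missing days.
    """

    location: str
    latitude: float
    year: int
    dates: np.ndarray
    tmin: np.ndarray
    tmax: np.ndarray

    def __post_init__(self) -> None:
        self.dates = np.asarray(self.dates, dtype="datetime64[D]")
        self.tmin = np.asarray(self.tmin, dtype=float)
        self.tmax = np.asarray(self.tmax, dtype=float)
        n = len(self.dates)
        if len(self.tmin) != n or len(self.tmax) != n:
            raise InputError(f"season {self.location}/{self.year}: length mismatch")
        if n > 1 and not np.all(np.diff(self.dates).astype(int) == 1):
            raise InputError(f"season {self.location}/{self.year}: dates not contiguous")
        both = ~np.isnan(self.tmin) & ~np.isnan(self.tmax)
        if np.any(self.tmax[both] < self.tmin[both]):
            raise InputError(f"season {self.location}/{self.year}: tmax < tmin")

    @property
    def n_days(self) -> int:
        return len(self.dates)

    @property
    def n_missing(self) -> int:
        """Days lacking tmin or tmax."""
        return int(np.sum(np.isnan(self.tmin) | np.isnan(self.tmax)))

    @property
    def doy(self) -> np.ndarray:
        """Day-of-year axis relative to Jan 1 of the bloom year."""
        return day_of_year(self.dates, self.year)

    def copy(self) -> "DailySeason":
        return DailySeason(
            self.location, self.latitude, self.year,
            self.dates.copy(), self.tmin.copy(), self.tmax.copy(),
        )


@dataclass
class HourlySeason:
    """Hourly temperatures (°C), 24 values per day on the season window."""

    location: str
    year: int
    temps: np.ndarray  # length = 24 * n_days
    doy: np.ndarray    # per-day day-of-year (length n_days)

    def __post_init__(self) -> None:
        self.temps = np.asarray(self.temps, dtype=float)
        self.doy = np.asarray(self.doy, dtype=int)
        if len(self.temps) != 24 * len(self.doy):
            raise InputError("hourly series length must be 24 x number of days")
        if not np.all(np.isfinite(self.temps)):
            raise InputError("hourly series contains non-finite values")

    @property
    def n_days(self) -> int:
        return len(self.doy)


@dataclass(frozen=True)
class SeasonSummary:
    location: str
    year: int
    seasonal_mean: float  # °C over Sep 1 - May 31


# ---------------------------------------------------------------------------
# Season assembly from tabular weather records
# ---------------------------------------------------------------------------

def seasons_from_frame(weather: pd.DataFrame) -> list[DailySeason]:
    """Assemble :class:`DailySeason` objects from a long-format weather table.

    Expects columns ``location, latitude, date, tmin, tmax`` (ISO dates, °C).
    Every date from September through May is assigned to the bloom year it
    precedes; days absent from the table count as missing.
    """
    req = {"location", "latitude", "date", "tmin", "tmax"}
    if not req.issubset(weather.columns):
        raise InputError(f"weather table needs columns {sorted(req)}")
    df = weather.copy()
    df["date"] = pd.to_datetime(df["date"]).dt.normalize()
    df["bloom_year"] = df["date"].dt.year + (df["date"].dt.month >= 9).astype(int)

    seasons: list[DailySeason] = []
    for (loc, year), grp in df.groupby(["location", "bloom_year"], sort=True):
        dates = season_dates(int(year))
        tmin = np.full(len(dates), np.nan)
        tmax = np.full(len(dates), np.nan)
        idx = (grp["date"].to_numpy().astype("datetime64[D]") - dates[0]).astype(int)
        ok = (idx >= 0) & (idx < len(dates))
        tmin[idx[ok]] = grp["tmin"].to_numpy()[ok]
        tmax[idx[ok]] = grp["tmax"].to_numpy()[ok]
        lat = float(grp["latitude"].iloc[0])
        seasons.append(DailySeason(str(loc), lat, int(year), dates, tmin, tmax))
    return seasons


def read_weather_csv(path) -> list[DailySeason]:
    """Read a ``location,latitude,date,tmin,tmax`` CSV into seasons."""
    return seasons_from_frame(pd.read_csv(path))


def seasons_to_frame(seasons: Iterable[DailySeason]) -> pd.DataFrame:
    rows = []
    for s in seasons:
        rows.append(pd.DataFrame({
            "location": s.location,
            "latitude": s.latitude,
            "date": s.dates.astype("datetime64[D]").astype(str),
            "tmin": s.tmin,
            "tmax": s.tmax,
        }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Filtering and gap filling
# ---------------------------------------------------------------------------

def filter_complete_seasons(
    seasons: Sequence[DailySeason], max_missing: int = 6
) -> list[DailySeason]:
    """Retain seasons with strictly fewer than ``max_missing`` missing days."""
    return [s for s in seasons if s.n_missing < max_missing]


def fill_gaps(season: DailySeason) -> DailySeason:
    """Fill missing tmin/tmax by linear interpolation between neighbours.

    Boundary gaps take the nearest present value.  Returns a new season
    with ``n_missing == 0``; the input is not modified.
    """
    out = season.copy()
    x = np.arange(season.n_days)
    for name in ("tmin", "tmax"):
        v = getattr(out, name)
        present = ~np.isnan(v)
        if not present.any():
            raise UnfillableSeasonError(
                f"season {season.location}/{season.year}: all {name} missing"
            )
        if not present.all():
            v[~present] = np.interp(x[~present], x[present], v[present])
    # interpolating tmin and tmax independently can cross on filled days
    lo = np.minimum(out.tmin, out.tmax)
    hi = np.maximum(out.tmin, out.tmax)
    out.tmin, out.tmax = lo, hi
    return out


# ---------------------------------------------------------------------------
# Solar geometry and hourly interpolation
# ---------------------------------------------------------------------------

def daylength_hours(doy: np.ndarray, latitude: float) -> np.ndarray:
    """Astronomical day length from the standard declination formula.

    δ = −23.44° · cos(2π (doy + 10) / 365); day length = 2ω0 where
    cos ω0 = −tan φ tan δ.  ``doy`` is the calendar day-of-year (may be
    negative/zero for autumn days counted from the bloom year's Jan 1;
    the formula is periodic so that is harmless).
    """
    if abs(latitude) > POLAR_LATITUDE:
        raise UnsupportedLatitudeError(
            f"latitude {latitude} beyond ±{POLAR_LATITUDE}°"
        )
    decl = np.deg2rad(-23.44) * np.cos(2 * np.pi * (np.asarray(doy) + 10) / 365.0)
    cos_h = np.clip(-np.tan(np.deg2rad(latitude)) * np.tan(decl), -1.0, 1.0)
    return 2.0 * np.rad2deg(np.arccos(cos_h)) / 15.0


def sun_times(doy: np.ndarray, latitude: float) -> tuple[np.ndarray, np.ndarray]:
    """(sunrise, sunset) in local solar hours, symmetric around noon."""
    dl = daylength_hours(doy, latitude)
    return 12.0 - dl / 2.0, 12.0 + dl / 2.0


def to_hourly(season: DailySeason, latitude: float | None = None) -> HourlySeason:
    """Interpolate daily tmin/tmax to 24 hourly temperatures per day.

    Daytime follows a half-sine rising from tmin at sunrise and peaking
    before sunset; night-time decays logarithmically from the sunset
    temperature toward the next day's tmin, reaching it exactly at the
    next sunrise.  Pre-dawn hours of the first day reuse that day's own
    sunset parameters as a stand-in for the missing previous day.
    """
    if season.n_missing:
        raise InputError("to_hourly requires a gap-free season (fill_gaps first)")
    lat = season.latitude if latitude is None else latitude
    doy = season.doy
    # calendar doy for solar geometry (positive all year)
    cal_doy = np.where(doy > 0, doy, doy + 365)
    sunrise, sunset = sun_times(cal_doy, lat)
    dl = sunset - sunrise

    n = season.n_days
    tmin, tmax = season.tmin, season.tmax
    t_sunset = tmin + (tmax - tmin) * np.sin(np.pi * dl / (dl + 4.0))

    temps = np.empty(n * 24)
    hours = np.arange(24.0)
    for i in range(n):
        prev = max(i - 1, 0)
        nxt = min(i + 1, n - 1)
        day = tmin[i] + (tmax[i] - tmin[i]) * np.sin(
            np.pi * (hours - sunrise[i]) / (dl[i] + 4.0)
        )
        # night after today's sunset: decay toward tomorrow's tmin
        night_len_next = 24.0 - sunset[i] + sunrise[nxt]
        since_sunset = np.maximum(hours - sunset[i], 1.0)
        late = t_sunset[i] - (t_sunset[i] - tmin[nxt]) / np.log(night_len_next) * np.log(
            since_sunset
        )
        # night before today's sunrise: tail of yesterday's decay
        night_len_prev = 24.0 - sunset[prev] + sunrise[i]
        since_prev_sunset = np.maximum(hours + 24.0 - sunset[prev], 1.0)
        early = t_sunset[prev] - (t_sunset[prev] - tmin[i]) / np.log(
            night_len_prev
        ) * np.log(since_prev_sunset)

        block = np.where(hours < sunrise[i], early, np.where(hours <= sunset[i], day, late))
        temps[i * 24:(i + 1) * 24] = block
    return HourlySeason(season.location, season.year, temps, doy)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def seasonal_mean(season: DailySeason) -> SeasonSummary:
    """Mean of daily (tmin+tmax)/2 over the Sep 1 - May 31 window."""
    if season.n_missing:
        raise InputError("seasonal_mean requires a gap-free season")
    m = float(np.mean((season.tmin + season.tmax) / 2.0))
    return SeasonSummary(season.location, season.year, m)


def monthly_mean_temps(season: DailySeason) -> np.ndarray:
    """Nine calendar-month means of daily (tmin+tmax)/2, Sep through May."""
    if season.n_missing:
        raise InputError("monthly means require a gap-free season")
    months = season.dates.astype("datetime64[M]").astype(int) % 12 + 1
    tmean = (season.tmin + season.tmax) / 2.0
    return np.array([tmean[months == m].mean() for m in SEASON_MONTHS])
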