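"""Season filtering, gap filling, hourly interpolation and summaries."""

import numpy as np
import pandas as pd
import pytest

from vdomains.errors import (InputError, UnfillableSeasonError,
                             UnsupportedLatitudeError)
from vdomains.thermal import (fill_gaps, filter_complete_seasons,
                              monthly_mean_temps, seasonal_mean,
                              seasons_from_frame, seasons_to_frame, sun_times,
                              to_hourly)

from conftest import make_flat_season


def _with_missing(season, idx):
    s = season.copy()
    for i in idx:
        s.tmin[i] = np.nan
        s.tmax[i] = np.nan
    return s


class TestFilterCompleteSeasons:
    @pytest.mark.parametrize("n_missing,kept", [(0, True), (5, True), (6, False), (10, False)])
    def test_strict_threshold(self, flat_season, n_missing, kept):
        """Seasons missing fewer than 6 days are retained; 6 or more dropped."""
        s = _with_missing(flat_season, range(n_missing))
        assert (len(filter_complete_seasons([s])) == 1) is kept

    def test_matches_brute_force_on_mixed_set(self, flat_season):
        counts = [0, 1, 5, 6, 7, 2, 9, 3, 6, 4]
        seasons = [_with_missing(flat_season, range(c)) for c in counts]
        kept = filter_complete_seasons(seasons)
        assert len(kept) == sum(1 for c in counts if c < 6)
        # order preserved
        assert [s.n_missing for s in kept] == [c for c in counts if c < 6]


class TestFillGaps:
    def test_no_gaps_is_identity(self, flat_season):
        out = fill_gaps(flat_season)
        np.testing.assert_array_equal(out.tmin, flat_season.tmin)
        np.testing.assert_array_equal(out.tmax, flat_season.tmax)

    def test_single_gap_is_midpoint(self):
        s = make_flat_season(tmin=10.0, tmax=10.0)
        s.tmin[100] = np.nan
        s.tmax[100] = np.nan
        s.tmin[99], s.tmin[101] = 10.0, 12.0
        s.tmax[99], s.tmax[101] = 10.0, 12.0
        out = fill_gaps(s)
        assert out.tmin[100] == pytest.approx(11.0)
        assert out.tmax[100] == pytest.approx(11.0)
        assert out.n_missing == 0

    def test_scattered_gaps_match_pandas_oracle(self):
        rng = np.random.default_rng(5)
        s = make_flat_season()
        s.tmin[:] = rng.normal(5, 3, s.n_days)
        s.tmax[:] = s.tmin + 6
        gaps = [0, 50, 51, 200, s.n_days - 1]
        expected = {}
        for name in ("tmin", "tmax"):
            ser = pd.Series(getattr(s, name).copy())
            ser[gaps] = np.nan
            expected[name] = ser.interpolate(limit_direction="both").to_numpy()
        for i in gaps:
            s.tmin[i] = np.nan
            s.tmax[i] = np.nan
        out = fill_gaps(s)
        np.testing.assert_allclose(out.tmin, expected["tmin"], atol=1e-12)
        np.testing.assert_allclose(out.tmax, expected["tmax"], atol=1e-12)

    def test_all_missing_variable_raises(self, flat_season):
        s = flat_season.copy()
        s.tmin[:] = np.nan
        with pytest.raises(UnfillableSeasonError):
            fill_gaps(s)


def _oracle_hourly(season, lat):
    """Straight-line reimplementation of the day-sine / night-log scheme."""
    import math

    n = season.n_days
    doy = season.doy
    cal = [d if d > 0 else d + 365 for d in doy]
    sunrise, sunset, dl, tsunset = [], [], [], []
    for i in range(n):
        decl = math.radians(-23.44) * math.cos(2 * math.pi * (cal[i] + 10) / 365.0)
        cosh = -math.tan(math.radians(lat)) * math.tan(decl)
        cosh = min(1.0, max(-1.0, cosh))
        daylen = 2 * math.degrees(math.acos(cosh)) / 15.0
        sr, ss = 12 - daylen / 2, 12 + daylen / 2
        sunrise.append(sr)
        sunset.append(ss)
        dl.append(daylen)
        tsunset.append(
            season.tmin[i]
            + (season.tmax[i] - season.tmin[i]) * math.sin(math.pi * daylen / (daylen + 4))
        )
    out = []
    for i in range(n):
        prev = i - 1 if i > 0 else 0
        nxt = i + 1 if i < n - 1 else n - 1
        for h in range(24):
            if sunrise[i] <= h <= sunset[i]:
                t = season.tmin[i] + (season.tmax[i] - season.tmin[i]) * math.sin(
                    math.pi * (h - sunrise[i]) / (dl[i] + 4)
                )
            elif h > sunset[i]:
                nl = 24 - sunset[i] + sunrise[nxt]
                hs = max(h - sunset[i], 1.0)
                t = tsunset[i] - (tsunset[i] - season.tmin[nxt]) / math.log(nl) * math.log(hs)
            else:
                nl = 24 - sunset[prev] + sunrise[i]
                hs = max(h + 24 - sunset[prev], 1.0)
                t = tsunset[prev] - (tsunset[prev] - season.tmin[i]) / math.log(nl) * math.log(hs)
            out.append(t)
    return np.array(out)


class TestToHourly:
    def test_degenerate_amplitude_is_constant(self):
        s = make_flat_season(tmin=10.0, tmax=10.0)
        hourly = to_hourly(s)
        np.testing.assert_allclose(hourly.temps, 10.0, atol=1e-12)

    def test_bounds_per_day(self, tiny_dataset):
        s = tiny_dataset.weather[0]
        hourly = to_hourly(s)
        temps = hourly.temps.reshape(-1, 24)
        for i in range(s.n_days):
            nxt = min(i + 1, s.n_days - 1)
            assert temps[i].max() <= s.tmax[i] + 1e-9
            assert temps[i].min() >= min(s.tmin[i], s.tmin[nxt]) - 1e-9
            # daily mean lies between the day's extremes
            assert s.tmin[i] - 1e-9 <= temps[i].mean() <= s.tmax[i] + 1e-9

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(9)
        s = make_flat_season(latitude=35.0)
        s.tmin[:] = rng.normal(4, 4, s.n_days)
        s.tmax[:] = s.tmin + rng.uniform(4, 12, s.n_days)
        hourly = to_hourly(s)
        np.testing.assert_allclose(hourly.temps, _oracle_hourly(s, 35.0), atol=1e-9)

    def test_latitude_continuity(self, flat_season):
        a = to_hourly(flat_season, latitude=35.0)
        b = to_hourly(flat_season, latitude=35.1)
        assert np.max(np.abs(a.temps - b.temps)) < 0.2

    def test_junction_continuity(self):
        """Hourly curve has no jump larger than typical hourly change."""
        rng = np.random.default_rng(2)
        s = make_flat_season()
        s.tmin[:] = rng.normal(4, 3, s.n_days)
        s.tmax[:] = s.tmin + 8
        temps = to_hourly(s).temps
        assert np.max(np.abs(np.diff(temps))) < 6.0

    def test_polar_latitude_rejected(self, flat_season):
        with pytest.raises(UnsupportedLatitudeError):
            to_hourly(flat_season, latitude=70.0)

    def test_requires_gap_free(self, flat_season):
        s = _with_missing(flat_season, [3])
        with pytest.raises(InputError):
            to_hourly(s)


class TestSeasonalMean:
    def test_constant_season(self):
        s = make_flat_season(tmin=8.0, tmax=12.0)
        assert seasonal_mean(s).seasonal_mean == pytest.approx(10.0)

    def test_invariant_to_location_label(self):
        a = make_flat_season(location="A")
        b = make_flat_season(location="B")
        assert seasonal_mean(a).seasonal_mean == seasonal_mean(b).seasonal_mean

    def test_synthetic_location_hits_configured_mean(self, mid_gradient_dataset):
        cfg = mid_gradient_dataset.config
        for loc, target in zip(cfg.location_ids, cfg.location_means):
            means = [
                seasonal_mean(s).seasonal_mean
                for s in mid_gradient_dataset.seasons_for(loc)
            ]
            assert np.mean(means) == pytest.approx(target, abs=0.3)


class TestMonthlyMeans:
    def test_against_groupby_oracle(self, tiny_dataset):
        s = tiny_dataset.weather[0]
        got = monthly_mean_temps(s)
        df = pd.DataFrame(
            {
                "month": pd.DatetimeIndex(s.dates).month,
                "tmean": (s.tmin + s.tmax) / 2,
            }
        )
        oracle = df.groupby("month")["tmean"].mean()
        for val, month in zip(got, (9, 10, 11, 12, 1, 2, 3, 4, 5)):
            assert val == pytest.approx(oracle[month])


class TestSeasonAssembly:
    def test_frame_roundtrip(self, tiny_dataset):
        frame = seasons_to_frame(tiny_dataset.weather[:4])
        back = seasons_from_frame(frame)
        assert len(back) == 4
        for orig, rec in zip(sorted(tiny_dataset.weather[:4], key=lambda s: (s.location, s.year)), back):
            assert rec.location == orig.location and rec.year == orig.year
            np.testing.assert_allclose(rec.tmin, orig.tmin)
            np.testing.assert_allclose(rec.tmax, orig.tmax)

    def test_absent_days_count_missing(self):
        s = make_flat_season()
        frame = seasons_to_frame([s]).iloc[10:]  # drop 10 days
        (rec,) = seasons_from_frame(frame)
        assert rec.n_missing == 10

    def test_sun_times_symmetric_about_noon(self):
        sr, ss = sun_times(np.arange(1, 366), 35.0)
        np.testing.assert_allclose(sr + ss, 24.0, atol=1e-9)
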