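"""All-vs-all cross-validation of calibrated models across locations.

Every calibrated model — process-based or Gaussian-process — is evaluated
against every location's observed bloom dates, giving a square matrix of
RMSE values indexed by (calibration location, validation location).
Failed process-model predictions are substituted with a fixed penalty
error (35 days); the GP never fails.  Matrix axes are ordered by the
locations' seasonal mean temperatures, the coordinate along which the
performance surface is later interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Protocol

import numpy as np
import pandas as pd

from .calibrate import FAILURE_PENALTY
from .errors import InputError
from .gp import SeasonFeatures, featurize
from .thermal import DailySeason, HourlySeason, seasonal_mean, to_hourly


class BloomModel(Protocol):
    """Anything that predicts bloom days for a location's seasons."""

    location: str
    t_calib: float | None

    def predict(self, dataset: "LocationDataset") -> np.ndarray:
        """Whole-day predictions aligned with the dataset's seasons;
        NaN marks a failed prediction."""


@dataclass
class LocationDataset:
    """One location's complete seasons with observations, hourly series
    and features precomputed for both modelling approaches."""

    location: str
    latitude: float
    seasons: list[DailySeason]
    observed: np.ndarray               # bloom day-of-year per season
    hourly: list[HourlySeason] = field(default_factory=list)
    features: list[SeasonFeatures] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        if len(self.observed) != len(self.seasons):
            raise InputError("observations must align with seasons")
        if not self.hourly:
            self.hourly = [to_hourly(s) for s in self.seasons]
        if not self.features:
            self.features = [featurize(s) for s in self.seasons]

    @property
    def n_seasons(self) -> int:
        return len(self.seasons)

    @property
    def years(self) -> list[int]:
        return [s.year for s in self.seasons]

    @property
    def seasonal_means(self) -> np.ndarray:
        return np.array([seasonal_mean(s).seasonal_mean for s in self.seasons])

    @property
    def t_mean(self) -> float:
        """Location-level seasonal mean temperature (average over seasons)."""
        return float(self.seasonal_means.mean())


def datasets_from_synthetic(dataset) -> dict[str, LocationDataset]:
    """Bundle a SyntheticDataset into per-location datasets (observed
    seasons only; seasons where the truth model failed carry no record)."""
    out: dict[str, LocationDataset] = {}
    for loc in sorted({s.location for s in dataset.weather}):
        obs = dataset.observed_for(loc).set_index("year")["bloom_doy"]
        seasons = [s for s in dataset.seasons_for(loc) if s.year in obs.index]
        if not seasons:
            continue
        observed = obs.loc[[s.year for s in seasons]].to_numpy(float)
        out[loc] = LocationDataset(loc, seasons[0].latitude, seasons, observed)
    return out


@dataclass(frozen=True)
class TransferCell:
    calib_location: str
    valid_location: str
    t_calib: float
    t_valid: float
    rmse: float
    n_failures: int
    n_seasons: int

    @property
    def delta(self) -> float:
        """Environmental shift: validation minus calibration mean (°C)."""
        return self.t_valid - self.t_calib


@dataclass
class TransferMatrix:
    """Square grid of transfer RMSE over (calibration x validation) locations."""

    approach: str                      # "process" or "ml"
    locations: list[str]               # ordered by calibration seasonal mean
    t_means: np.ndarray                # seasonal mean per location, same order
    cells: list[TransferCell]

    @property
    def n_locations(self) -> int:
        return len(self.locations)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def rmse_grid(self) -> pd.DataFrame:
        """Square calibration x validation RMSE table."""
        g = pd.DataFrame(index=self.locations, columns=self.locations, dtype=float)
        for c in self.cells:
            g.loc[c.calib_location, c.valid_location] = c.rmse
        return g

    def to_frame(self) -> pd.DataFrame:
        """Long-format table, one row per calibration-validation pair."""
        return pd.DataFrame(
            {
                "calib_location": [c.calib_location for c in self.cells],
                "valid_location": [c.valid_location for c in self.cells],
                "t_calib": [c.t_calib for c in self.cells],
                "t_valid": [c.t_valid for c in self.cells],
                "delta": [c.delta for c in self.cells],
                "rmse": [c.rmse for c in self.cells],
                "n_failures": [c.n_failures for c in self.cells],
                "n_seasons": [c.n_seasons for c in self.cells],
            }
        )

    def diagonal(self) -> pd.Series:
        d = {c.calib_location: c.rmse for c in self.cells
             if c.calib_location == c.valid_location}
        return pd.Series([d[l] for l in self.locations], index=self.locations)

    def off_diagonal_rmse(self) -> np.ndarray:
        return np.array(
            [c.rmse for c in self.cells if c.calib_location != c.valid_location]
        )


def rmse_with_penalty(
    predicted: np.ndarray, observed: np.ndarray, penalty: float = FAILURE_PENALTY
) -> tuple[float, int]:
    """(RMSE, failure count); NaN predictions contribute ``penalty`` days."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.size == 0 or predicted.shape != observed.shape:
        raise InputError("predicted/observed must be equal-length and non-empty")
    failed = np.isnan(predicted)
    err = np.where(failed, penalty, predicted - observed)
    return float(np.sqrt(np.mean(err**2))), int(failed.sum())


def evaluate_pair(
    model: BloomModel,
    target: LocationDataset,
    penalty: float = FAILURE_PENALTY,
    t_calib: float | None = None,
) -> TransferCell:
    """Evaluate one calibrated model on one validation dataset."""
    pred = model.predict(target)
    rmse, n_fail = rmse_with_penalty(pred, target.observed, penalty)
    tc = t_calib if t_calib is not None else model.t_calib
    if tc is None:
        raise InputError(f"model {model.location}: calibration mean unknown")
    return TransferCell(
        calib_location=model.location,
        valid_location=target.location,
        t_calib=float(tc),
        t_valid=target.t_mean,
        rmse=rmse,
        n_failures=n_fail,
        n_seasons=target.n_seasons,
    )


def build_matrix(
    models: Mapping[str, BloomModel],
    datasets: Mapping[str, LocationDataset],
    approach: str,
    penalty: float = FAILURE_PENALTY,
) -> TransferMatrix:
    """Cross-validate every model against every location's data.

    ``models`` and ``datasets`` must cover the same locations; with n
    locations the matrix holds n² cells.  Rows and columns are ordered by
    the locations' seasonal mean temperature.
    """
    missing = sorted(set(models) ^ set(datasets))
    if missing:
        raise InputError(f"locations without both model and dataset: {missing}")
    t_mean = {loc: datasets[loc].t_mean for loc in datasets}
    order = sorted(datasets, key=lambda l: t_mean[l])
    cells = [
        evaluate_pair(models[ci], datasets[vi], penalty)
        for ci in order
        for vi in order
    ]
    return TransferMatrix(
        approach=approach,
        locations=order,
        t_means=np.array([t_mean[l] for l in order]),
        cells=cells,
    )
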