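"""Gaussian-process comparator: seasonal temperature features -> bloom day.

The machine-learning counterpart to the process model is a
radial-basis-kernel Gaussian-process regression.  Each season is reduced
to nine features — the calendar-month mean temperatures from September
through May — standardised, and mapped to bloom day-of-year.
Hyperparameters (signal variance, length scale, noise variance) are
selected by maximising the log marginal likelihood from a seeded
multi-start.  The prior mean is the training-target mean; predictions are
posterior means rounded to whole days and never fail, in contrast to the
process model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .errors import FitError, InputError
from .thermal import DailySeason, monthly_mean_temps

N_FEATURES = 9

#: Floor on the fitted noise variance, for conditioning of the kernel matrix.
NOISE_FLOOR = 1e-6

#: Ceiling on the fitted noise variance (relative to the normalised target
#: variance).  Kept small so the GP nearly interpolates its training data,
#: matching the behaviour of kernlab-style GP regression with its fixed
#: small regularisation term.
NOISE_CEILING = 1e-2


@dataclass(frozen=True)
class SeasonFeatures:
    """Monthly mean temperatures (Sep..May) for one location-year."""

    location: str
    year: int
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_FEATURES,) or not np.all(np.isfinite(v)):
            raise InputError("features must be 9 finite monthly means")
        object.__setattr__(self, "values", v)


def featurize(season: DailySeason) -> SeasonFeatures:
    """Nine monthly means of daily (tmin+tmax)/2, Sep through May."""
    return SeasonFeatures(season.location, season.year, monthly_mean_temps(season))


def feature_matrix(features: Sequence[SeasonFeatures]) -> np.ndarray:
    return np.vstack([f.values for f in features])


@dataclass
class GPModel:
    """A fitted GP regression from season features to bloom day-of-year."""

    location: str
    regressor: GaussianProcessRegressor
    x_mean: np.ndarray
    x_scale: np.ndarray
    rmse: float
    n_seasons: int
    t_calib: float | None = None

    @property
    def hyperparameters(self) -> dict:
        k = self.regressor.kernel_
        return {
            "signal_variance": float(k.k1.k1.constant_value),
            "length_scale": float(k.k1.k2.length_scale),
            "noise_variance": float(k.k2.noise_level),
        }

    def predict_features(self, features: Sequence[SeasonFeatures]) -> np.ndarray:
        """Posterior-mean bloom days, rounded to whole days; never fails."""
        X = feature_matrix(features)
        if X.shape[1] != N_FEATURES:
            raise InputError("feature-length mismatch")
        Xs = (X - self.x_mean) / self.x_scale
        return np.round(self.regressor.predict(Xs))

    def predict(self, dataset) -> np.ndarray:
        """Predictions for a LocationDataset (transfer-module interface)."""
        return self.predict_features(dataset.features)


def fit_gp(
    features: Sequence[SeasonFeatures],
    bloom_doy,
    seed: int = 0,
    location: str | None = None,
    t_calib: float | None = None,
    n_restarts: int = 3,
) -> GPModel:
    """Fit the RBF-kernel GP to one location's (or group's) seasons.

    Requires at least 5 training seasons and non-degenerate features.
    The marginal-likelihood search restarts ``n_restarts`` times from
    seeded random hyperparameter draws, so the fit is reproducible.
    """
    if len(features) < 5:
        raise FitError("need at least 5 training seasons")
    y = np.asarray(bloom_doy, dtype=float)
    if len(y) != len(features):
        raise FitError("features and targets differ in length")
    X = feature_matrix(features)
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0)
    if np.any(x_scale <= 0):
        raise FitError("degenerate features: a monthly mean has zero variance")
    Xs = (X - x_mean) / x_scale

    kernel = (
        ConstantKernel(1.0, (1e-3, 1e4))
        * RBF(length_scale=1.0, length_scale_bounds=(1e-2, 1e3))
        + WhiteKernel(1e-3, (NOISE_FLOOR, NOISE_CEILING))
    )
    gpr = GaussianProcessRegressor(
        kernel=kernel,
        normalize_y=True,
        n_restarts_optimizer=n_restarts,
        random_state=int(seed) % (2**31 - 1),
    )
    gpr.fit(Xs, y)
    pred = np.round(gpr.predict(Xs))
    rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
    name = location or features[0].location
    return GPModel(
        location=name,
        regressor=gpr,
        x_mean=x_mean,
        x_scale=x_scale,
        rmse=rmse,
        n_seasons=len(y),
        t_calib=t_calib,
    )
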