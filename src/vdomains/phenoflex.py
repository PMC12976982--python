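"""Process-based bloom model: kinetic chill, GDH heat, sigmoidal transition.

The model couples two classic sub-models of temperate-tree dormancy.
Chill accumulates through a two-step kinetic scheme (the Dynamic Model):
an hourly recurrence builds a thermolabile precursor ``x`` whose
equilibrium level and formation rate are Arrhenius functions of absolute
temperature; whenever ``x`` reaches unity, a temperature-gated sigmoid
converts part of it into an irreversible *chill portion* added to ``y``.
Heat accumulates as Growing Degree Hours (GDH): a cosine response of
hourly temperature between a base ``Tb``, optimum ``Tu`` and critical
``Tc`` temperature.  The two phases overlap through a logistic transition
weight ``w(y) = 1 / (1 + exp(-s1 (y - yc)))`` — heat counts towards the
forcing sum ``z`` only to the degree that the chill requirement ``yc``
has been met.  Bloom is predicted at the first hour where ``z``
reaches the heat requirement ``zc``; if that never happens within the
season the prediction is a FAILURE.

The hourly recurrences are compiled with numba; ``predict_bloom`` is the
high-level entry point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from enum import Enum

import numpy as np
from numba import njit

from .errors import InputError, NumericError, ParameterError
from .thermal import HourlySeason

KELVIN = 273.15

#: Parameter order used for flat-vector interfaces (optimizers, kernels).
PARAM_NAMES = (
    "yc", "zc", "s1", "Tu", "E0", "E1", "A0", "A1", "Tf", "Tc", "Tb", "slope",
)


@dataclass(frozen=True)
class PhenoFlexParams:
    """The 12-parameter vector of the process-based bloom model.

    yc : chill portions required (transition midpoint)
    zc : Growing Degree Hours required for bloom
    s1 : steepness of the logistic chill->heat transition (per portion)
    Tu : heat optimum temperature, °C
    E0, E1 : activation energies of precursor formation/destruction, K
    A0, A1 : Arrhenius amplitudes of the two rate constants, 1/h
    Tf : transition temperature of the chill-conversion sigmoid, °C
         (converted to Kelvin inside the kinetics)
    Tc : upper critical heat temperature, °C
    Tb : heat base temperature, °C
    slope : steepness of the chill-conversion sigmoid, dimensionless
    """

    yc: float
    zc: float
    s1: float
    Tu: float
    E0: float
    E1: float
    A0: float
    A1: float
    Tf: float
    Tc: float
    Tb: float
    slope: float

    def __post_init__(self) -> None:
        if not (self.Tb < self.Tu < self.Tc):
            raise ParameterError(f"need Tb < Tu < Tc, got {self.Tb}, {self.Tu}, {self.Tc}")
        if self.yc <= 0 or self.zc <= 0:
            raise ParameterError("yc and zc must be positive")
        if self.A0 <= 0 or self.A1 <= 0:
            raise ParameterError("A0 and A1 must be positive")
        if not (0 < self.E0 < self.E1):
            raise ParameterError("need E1 > E0 > 0")
        if self.s1 <= 0:
            raise ParameterError("s1 must be positive")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, vec) -> "PhenoFlexParams":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (len(PARAM_NAMES),):
            raise ParameterError(f"expected {len(PARAM_NAMES)} parameters")
        return cls(**dict(zip(PARAM_NAMES, vec.tolist())))

    def to_dict(self) -> dict:
        return asdict(self)


class BloomStatus(str, Enum):
    BLOOM = "BLOOM"
    FAILURE = "FAILURE"


@dataclass(frozen=True)
class DormancyState:
    """Precursor level, chill portions and weighted heat after the run."""
    x: float
    y: float
    z: float
    hour: int


@dataclass(frozen=True)
class BloomPrediction:
    status: BloomStatus
    bloom_doy: int | None
    bloom_doy_fractional: float | None
    state: DormancyState

    @property
    def bloomed(self) -> bool:
        return self.status is BloomStatus.BLOOM


# ---------------------------------------------------------------------------
# Hourly response functions
# ---------------------------------------------------------------------------

def gdh_hour(T, params: PhenoFlexParams):
    """Growing Degree Hours contributed by one hour at temperature ``T`` (°C).

    Zero at or below ``Tb`` and at or above ``Tc``; a rising cosine branch
    on (Tb, Tu] peaking at ``Tu - Tb``; a falling cosine branch on (Tu, Tc).
    Accepts scalars or arrays.  The Anderson stress factor is fixed at 1.
    """
    T = np.asarray(T, dtype=float)
    Tb, Tu, Tc = params.Tb, params.Tu, params.Tc
    up = (Tu - Tb) / 2.0 * (1.0 + np.cos(np.pi + np.pi * (T - Tb) / (Tu - Tb)))
    down = (Tu - Tb) * (1.0 + np.cos(np.pi / 2.0 + np.pi / 2.0 * (T - Tu) / (Tc - Tu)))
    out = np.where(T <= Tu, up, down)
    out = np.where((T <= Tb) | (T >= Tc), 0.0, out)
    return float(out) if out.ndim == 0 else out


@njit(cache=True)
def _run_kernel(temps, yc, zc, s1, Tu, E0, E1, A0, A1, TfK, Tc, Tb, slope):
    """Hour-by-hour dormancy recurrence.

    Returns (bloom_hour, x, y, z).  bloom_hour is the index of the first
    hour where z >= zc, or -1 for failure, or -2 on a non-finite
    intermediate.
    """
    x = 0.0
    y = 0.0
    z = 0.0
    bloom = -1
    for i in range(temps.size):
        TK = temps[i] + KELVIN
        xs = (A0 / A1) * math.exp(-(E0 - E1) / TK)
        k1 = A1 * math.exp(-E1 / TK)
        x = xs - (xs - x) * math.exp(-k1)
        if x >= 1.0:
            sr = math.exp(slope * TfK * (TK - TfK) / TK)
            f = sr / (1.0 + sr)
            y += x * f
            x *= 1.0 - f
        T = temps[i]
        if T <= Tb or T >= Tc:
            g = 0.0
        elif T <= Tu:
            g = (Tu - Tb) / 2.0 * (1.0 + math.cos(math.pi + math.pi * (T - Tb) / (Tu - Tb)))
        else:
            g = (Tu - Tb) * (1.0 + math.cos(math.pi / 2.0 + math.pi / 2.0 * (T - Tu) / (Tc - Tu)))
        w = 1.0 / (1.0 + math.exp(-s1 * (y - yc)))
        z += g * w
        if not (math.isfinite(x) and math.isfinite(y) and math.isfinite(z)):
            return -2, x, y, z
        if bloom < 0 and z >= zc:
            bloom = i
            break
    return bloom, x, y, z


@njit(cache=True)
def _run_kernel_trace(temps, yc, zc, s1, Tu, E0, E1, A0, A1, TfK, Tc, Tb, slope):
    """Like :func:`_run_kernel` but records the full (x, y, z) trajectory."""
    n = temps.size
    xs_t = np.empty(n)
    y_t = np.empty(n)
    z_t = np.empty(n)
    x = 0.0
    y = 0.0
    z = 0.0
    for i in range(n):
        TK = temps[i] + KELVIN
        xs = (A0 / A1) * math.exp(-(E0 - E1) / TK)
        k1 = A1 * math.exp(-E1 / TK)
        x = xs - (xs - x) * math.exp(-k1)
        if x >= 1.0:
            sr = math.exp(slope * TfK * (TK - TfK) / TK)
            f = sr / (1.0 + sr)
            y += x * f
            x *= 1.0 - f
        T = temps[i]
        if T <= Tb or T >= Tc:
            g = 0.0
        elif T <= Tu:
            g = (Tu - Tb) / 2.0 * (1.0 + math.cos(math.pi + math.pi * (T - Tb) / (Tu - Tb)))
        else:
            g = (Tu - Tb) * (1.0 + math.cos(math.pi / 2.0 + math.pi / 2.0 * (T - Tu) / (Tc - Tu)))
        w = 1.0 / (1.0 + math.exp(-s1 * (y - yc)))
        z += g * w
        xs_t[i] = x
        y_t[i] = y
        z_t[i] = z
    return xs_t, y_t, z_t


def _kernel_args(params: PhenoFlexParams) -> tuple:
    return (
        params.yc, params.zc, params.s1, params.Tu, params.E0, params.E1,
        params.A0, params.A1, params.Tf + KELVIN, params.Tc, params.Tb,
        params.slope,
    )


def chill_portions(temps_C: np.ndarray, params: PhenoFlexParams) -> float:
    """Chill portions accumulated by the Dynamic-Model recurrence alone."""
    temps = np.ascontiguousarray(temps_C, dtype=float)
    if temps.size == 0:
        return 0.0
    _, _, y, _ = _run_kernel(temps, *_kernel_args(params))
    return y


def dormancy_trace(temps_C: np.ndarray, params: PhenoFlexParams):
    """(x, y, z) trajectories over an hourly series; for diagnostics/tests."""
    temps = np.ascontiguousarray(temps_C, dtype=float)
    return _run_kernel_trace(temps, *_kernel_args(params))


def predict_bloom(hourly: HourlySeason, params: PhenoFlexParams) -> BloomPrediction:
    """Predict the bloom day for one season.

    Iterates hours from Sep 1 with initial x = y = z = 0, accumulating
    chill and transition-weighted heat; bloom is the day containing the
    first hour where z >= zc.  Returns a FAILURE prediction if the heat
    requirement is never met within the window.
    """
    if hourly.n_days < 30:
        raise InputError("season shorter than 30 days")
    temps = np.ascontiguousarray(hourly.temps, dtype=float)
    bloom, x, y, z = _run_kernel(temps, *_kernel_args(params))
    if bloom == -2:
        raise NumericError(f"non-finite state for params {params.to_dict()}")
    if bloom < 0:
        state = DormancyState(x, y, z, temps.size - 1)
        return BloomPrediction(BloomStatus.FAILURE, None, None, state)
    day = bloom // 24
    doy = int(hourly.doy[day])
    frac = doy + (bloom % 24) / 24.0
    return BloomPrediction(BloomStatus.BLOOM, doy, frac, DormancyState(x, y, z, bloom))


def predict_many(
    hourly_seasons, params: PhenoFlexParams, fractional: bool = False
) -> np.ndarray:
    """Vector of predicted bloom days (NaN where the model fails to bloom)."""
    out = np.full(len(hourly_seasons), np.nan)
    for i, hs in enumerate(hourly_seasons):
        p = predict_bloom(hs, params)
        if p.bloomed:
            out[i] = p.bloom_doy_fractional if fractional else p.bloom_doy
    return out
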