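"""Kriged performance surfaces and validity-domain delineation.

The transfer matrix samples model error at scattered points of the
(calibration mean temperature, validation mean temperature) plane — one
point per location pair.  Ordinary kriging with an exponential variogram
turns those samples into a continuous RMSE surface on a regular grid.
A validity domain is then the connected region around the identity
diagonal where the kriged RMSE stays at or below a threshold (5 days by
default); its width in Δ = T_valid − T_calib, per calibration
temperature, measures how far a model calibrated there can be
transferred.

Kriging is implemented in its dual form: one linear solve against the
variogram matrix yields coefficients with which any target point is
predicted by a dot product.  With a zero nugget the predictor is exact at
the source points.  The empirical variogram is fitted by weighted least
squares (Cressie weights), with the nugget capped at 10% of the sill so
source values are honoured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from skimage import measure

from .errors import FitError, InputError
from .transfer import TransferMatrix

DEFAULT_THRESHOLD = 5.0   # days
DEFAULT_RESOLUTION = 0.05  # °C
MIN_COMPONENT_FRACTION = 0.01  # "minor exceptions" smaller than this are dropped


# ---------------------------------------------------------------------------
# Variogram
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExponentialVariogram:
    """γ(h) = nugget + partial_sill · (1 − exp(−h / range_))."""

    nugget: float
    partial_sill: float
    range_: float

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def __call__(self, h):
        h = np.asarray(h, dtype=float)
        g = self.nugget + self.partial_sill * (1.0 - np.exp(-h / self.range_))
        return np.where(h == 0.0, 0.0, g)  # γ(0) = 0 by definition


def empirical_variogram(
    x: np.ndarray, y: np.ndarray, v: np.ndarray, n_bins: int = 15
) -> pd.DataFrame:
    """Binned semivariance vs. separation distance."""
    pts = np.c_[x, y]
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    iu = np.triu_indices(len(v), k=1)
    dist = d[iu]
    gamma = 0.5 * (v[iu[0]] - v[iu[1]]) ** 2
    hmax = dist.max() * 0.75
    edges = np.linspace(0.0, hmax, n_bins + 1)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (dist > lo) & (dist <= hi)
        if m.sum() >= 2:
            rows.append((0.5 * (lo + hi), float(gamma[m].mean()), int(m.sum())))
    if len(rows) < 3:
        raise FitError("too few distance bins for a variogram fit")
    return pd.DataFrame(rows, columns=["h", "gamma", "n"])


def fit_variogram(
    x: np.ndarray, y: np.ndarray, v: np.ndarray, nugget_cap: float = 0.1
) -> ExponentialVariogram:
    """WLS fit of the exponential model to the empirical variogram.

    Weights are Cressie's n(h)/γ_model²; the nugget is constrained to at
    most ``nugget_cap`` of the sill so that kriging honours the sources.
    """
    emp = empirical_variogram(x, y, v)
    h, g, n = emp["h"].to_numpy(), emp["gamma"].to_numpy(), emp["n"].to_numpy()
    g_scale = max(g.max(), 1e-12)
    h_scale = max(h.max(), 1e-12)

    def resid(theta):
        nug, psill, rng = theta
        model = nug + psill * (1.0 - np.exp(-h / rng))
        w = np.sqrt(n) / np.maximum(model, 1e-9 * g_scale)
        return w * (g - model)

    x0 = np.array([0.0, g_scale, h_scale / 3.0])
    res = least_squares(
        resid,
        x0,
        bounds=([0.0, 1e-12 * g_scale, 1e-3 * h_scale], [np.inf, np.inf, 10 * h_scale]),
    )
    nug, psill, rng = res.x
    cap = nugget_cap * (nug + psill)
    if nug > cap:  # shift excess nugget into the partial sill
        psill += nug - cap
        nug = cap
    return ExponentialVariogram(float(nug), float(psill), float(rng))


# ---------------------------------------------------------------------------
# Ordinary kriging (dual form)
# ---------------------------------------------------------------------------

def prepare_points(
    matrix: TransferMatrix,
    approach: str | None = None,
    densify_diagonal: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Source points (t_calib, t_valid, rmse) for kriging.

    Process-based: diagonal cells keep each model's own-location RMSE.
    Machine-learning: diagonal cells are set to zero before kriging —
    a GP interpolates its own training data essentially perfectly, and
    anchoring the diagonal keeps the smoother from distorting the
    near-diagonal structure.

    ``densify_diagonal`` optionally adds interpolated points along the
    identity line at the given spacing (°C) before kriging, so the
    smoother honours the diagonal between locations as well (zeros for
    the ML approach; linearly interpolated own-location RMSE for the
    process-based approach).
    """
    approach = approach or matrix.approach
    x, y, v = [], [], []
    for c in matrix.cells:
        val = c.rmse
        if approach == "ml" and c.calib_location == c.valid_location:
            val = 0.0
        x.append(c.t_calib)
        y.append(c.t_valid)
        v.append(val)
    x, y, v = np.array(x), np.array(y), np.array(v)
    if densify_diagonal:
        t = np.sort(matrix.t_means)
        diag_v = np.array(
            [0.0 if approach == "ml" else matrix.diagonal().iloc[i]
             for i in range(len(t))]
        )
        tt = np.arange(t[0], t[-1] + densify_diagonal / 2, densify_diagonal)
        vv = np.interp(tt, t, diag_v)
        # drop densified points duplicating existing diagonal sources
        keep = ~np.isin(np.round(tt, 9), np.round(t, 9))
        x = np.concatenate([x, tt[keep]])
        y = np.concatenate([y, tt[keep]])
        v = np.concatenate([v, vv[keep]])
    return x, y, v


@dataclass
class PerformanceSurface:
    """Kriged RMSE over a square (T_calib, T_valid) grid."""

    t_axis: np.ndarray                 # shared axis for both dimensions
    grid: np.ndarray                   # grid[i, j] = RMSE at (t_axis[i], t_axis[j])
    variogram: ExponentialVariogram
    source_x: np.ndarray
    source_y: np.ndarray
    source_v: np.ndarray
    _dual_b: np.ndarray = field(repr=False, default=None)
    _dual_a: float = field(repr=False, default=0.0)

    @property
    def resolution(self) -> float:
        return float(self.t_axis[1] - self.t_axis[0])

    def predict(self, t_calib, t_valid) -> np.ndarray:
        """Evaluate the kriging predictor at arbitrary coordinates."""
        t_calib = np.atleast_1d(np.asarray(t_calib, dtype=float))
        t_valid = np.atleast_1d(np.asarray(t_valid, dtype=float))
        d = np.sqrt(
            (t_calib[:, None] - self.source_x[None, :]) ** 2
            + (t_valid[:, None] - self.source_y[None, :]) ** 2
        )
        return self.variogram(d) @ self._dual_b + self._dual_a

    @property
    def in_range(self):
        return (float(self.t_axis[0]), float(self.t_axis[-1]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.grid, index=self.t_axis, columns=self.t_axis)


def _average_duplicates(x, y, v):
    key = np.round(np.c_[x, y], 9)
    uniq, inv = np.unique(key, axis=0, return_inverse=True)
    sums = np.zeros(len(uniq))
    counts = np.zeros(len(uniq))
    np.add.at(sums, inv, v)
    np.add.at(counts, inv, 1.0)
    return uniq[:, 0], uniq[:, 1], sums / counts


def krige(
    x: np.ndarray,
    y: np.ndarray,
    v: np.ndarray,
    resolution: float = DEFAULT_RESOLUTION,
    variogram: ExponentialVariogram | None = None,
    extent: tuple[float, float] | None = None,
) -> PerformanceSurface:
    """Ordinary kriging of scattered RMSE points onto a square grid.

    Points sharing a coordinate are averaged first.  The grid spans
    ``extent`` (default: the bounding interval of all coordinates) at the
    requested resolution, identically in both dimensions so the identity
    diagonal lies on grid nodes.
    """
    x, y, v = (np.asarray(a, dtype=float) for a in (x, y, v))
    if len(v) < 10:
        raise InputError("kriging needs at least 10 source points")
    x, y, v = _average_duplicates(x, y, v)
    vgm = variogram or (
        fit_variogram(x, y, v)
        if np.ptp(v) > 0
        else ExponentialVariogram(0.0, 1e-12, 1.0)
    )

    n = len(v)
    pts = np.c_[x, y]
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    gamma = vgm(d)
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = gamma
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    A[n, n] = 0.0
    rhs = np.append(v, 0.0)
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        A[:n, :n] += np.eye(n) * 1e-10 * max(vgm.sill, 1.0)
        sol = np.linalg.solve(A, rhs)
    b, a = sol[:n], sol[n]

    if extent is None:
        lo = min(x.min(), y.min())
        hi = max(x.max(), y.max())
    else:
        lo, hi = extent
    n_steps = int(np.ceil((hi - lo) / resolution - 1e-9))
    t_axis = lo + np.arange(n_steps + 1) * resolution  # last node >= hi

    surf = PerformanceSurface(t_axis, None, vgm, x, y, v, b, float(a))
    # evaluate on the grid in row chunks to bound memory
    grid = np.empty((len(t_axis), len(t_axis)))
    for i in range(len(t_axis)):
        grid[i, :] = surf.predict(np.full(len(t_axis), t_axis[i]), t_axis)
    surf.grid = grid
    return surf


def krige_matrix(
    matrix: TransferMatrix,
    resolution: float = DEFAULT_RESOLUTION,
    variogram: ExponentialVariogram | None = None,
    densify_diagonal: float | None = 0.25,
) -> PerformanceSurface:
    """Convenience: prepare points per the approach's diagonal rule
    (densifying the identity line so the smoother honours it between
    locations) and krige."""
    x, y, v = prepare_points(matrix, densify_diagonal=densify_diagonal)
    return krige(x, y, v, resolution=resolution, variogram=variogram)


# ---------------------------------------------------------------------------
# Validity domains
# ---------------------------------------------------------------------------

@dataclass
class ValidityDomain:
    """Connected sub-threshold region of a performance surface."""

    threshold: float
    t_axis: np.ndarray
    mask: np.ndarray                   # raw threshold mask
    retained: np.ndarray               # after component filtering

    def widths(self) -> pd.DataFrame:
        """Per-calibration-temperature Δ interval where RMSE ≤ threshold."""
        rows = []
        t = self.t_axis
        for i, tc in enumerate(t):
            j = np.flatnonzero(self.retained[i, :])
            if j.size:
                dlo, dhi = t[j[0]] - tc, t[j[-1]] - tc
                rows.append((tc, dlo, dhi, dhi - dlo))
            else:
                rows.append((tc, np.nan, np.nan, 0.0))
        return pd.DataFrame(rows, columns=["t_calib", "delta_lo", "delta_hi", "width"])

    @property
    def is_empty(self) -> bool:
        return not bool(self.retained.any())


def delineate(
    surface: PerformanceSurface,
    threshold: float = DEFAULT_THRESHOLD,
    min_component_fraction: float = MIN_COMPONENT_FRACTION,
) -> ValidityDomain:
    """Threshold the kriged surface and keep the diagonal-anchored region.

    Connected components (8-connectivity) of the sub-threshold mask are
    retained when they touch the identity diagonal and cover at least
    ``min_component_fraction`` of the grid; smaller patches are treated
    as minor exceptions and dropped.  An empty domain is a valid result.
    """
    mask = surface.grid <= threshold
    labels = measure.label(mask, connectivity=2)
    retained = np.zeros_like(mask)
    diag = np.arange(len(surface.t_axis))
    diag_labels = set(labels[diag, diag]) - {0}
    min_cells = min_component_fraction * mask.size
    for lab in diag_labels:
        comp = labels == lab
        if comp.sum() >= min_cells:
            retained |= comp
    return ValidityDomain(threshold, surface.t_axis, mask, retained)


def domain_summary(domain: ValidityDomain) -> pd.DataFrame:
    """Width table restricted to calibration temperatures with any validity."""
    w = domain.widths()
    return w[w["width"] > 0].reset_index(drop=True)


def plot_surface(
    surface: PerformanceSurface,
    domain: ValidityDomain | None = None,
    cap: float = 20.0,
    ax=None,
):
    """Heatmap of the kriged RMSE surface with the validity-domain outline.

    Values above ``cap`` (20 days by default) saturate at the top of the
    colour scale so extreme failures do not flatten the gradient; the
    domain boundary (RMSE = threshold) is drawn as a white contour.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    t = surface.t_axis
    im = ax.pcolormesh(
        t, t, np.minimum(surface.grid.T, cap), cmap="viridis",
        vmin=0.0, vmax=cap, shading="auto",
    )
    ax.plot(t, t, ls=":", color="grey", lw=1)
    if domain is not None and not domain.is_empty:
        ax.contour(
            t, t, domain.retained.T.astype(float), levels=[0.5],
            colors="white", linewidths=1.5,
        )
    ax.set_xlabel("calibration seasonal mean (°C)")
    ax.set_ylabel("validation seasonal mean (°C)")
    ax.figure.colorbar(im, ax=ax, label="RMSE (days)")
    return ax


def tercile_widths(domain: ValidityDomain) -> pd.Series:
    """Mean domain width in the cold/mid/warm thirds of calibration range."""
    w = domain.widths()
    t = w["t_calib"].to_numpy()
    edges = np.quantile(t, [0.0, 1 / 3, 2 / 3, 1.0])
    labels = ["cold", "mid", "warm"]
    out = {}
    for k, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        m = (t >= lo) & (t <= hi) if k == 2 else (t >= lo) & (t < hi)
        out[labels[k]] = float(w["width"].to_numpy()[m].mean())
    return pd.Series(out)
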