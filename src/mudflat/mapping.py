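"""Spatial autocorrelation estimation and ordinary-kriging interpolation.

The workflow mirrors how station data are turned into maps: estimate an
empirical correlogram from the station values, fit an exponential variogram
model to it by pair-count-weighted least squares, and krige onto a fine
regular grid (default 25 m).

Conventions
-----------
The exponential variogram is parameterized by its e-folding distance ``r``:

    gamma(h) = nugget + psill * (1 - exp(-h / r)),   h > 0

matching the covariance used by :mod:`mudflat.random_fields`, so fitted
ranges are directly comparable with generative ones. The correlogram is the
variogram transform ``rho(h) = 1 - gamma(h) / s^2`` with ``s^2`` the sample
variance; a per-distance-class Moran's I estimator is available under the
``estimator="morans_i"`` label as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .errors import DegenerateFieldError, MudflatError
from .raster import Raster

__all__ = [
    "Correlogram",
    "VariogramModel",
    "estimate_correlogram",
    "empirical_variogram",
    "fit_variogram",
    "OrdinaryKriging",
    "interpolate",
]

MIN_PAIRS_RELIABLE = 10


@dataclass
class Correlogram:
    """Spatial correlation per lag-distance bin."""

    bin_edges: np.ndarray          # (k+1,) metres
    correlation: np.ndarray        # (k,) in [-1, 1]
    pair_counts: np.ndarray        # (k,) pairs per bin
    estimator: str                 # "semivariance" or "morans_i"
    sample_variance: float
    semivariance: Optional[np.ndarray] = None  # (k,), set by the variogram route

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def reliable(self) -> np.ndarray:
        """Bins with enough pairs to be trusted (>= 10)."""
        return self.pair_counts >= MIN_PAIRS_RELIABLE


@dataclass
class VariogramModel:
    """Fitted parametric variogram (exponential or spherical family)."""

    nugget: float
    psill: float
    range_m: float
    family: str = "exponential"
    converged: bool = True
    range_identifiable: bool = True

    def __post_init__(self) -> None:
        if self.nugget < 0 or self.psill < 0:
            raise ValueError("nugget and partial sill must be non-negative")
        if self.range_m <= 0:
            raise ValueError("range must be positive")
        if self.converged and self.nugget + self.psill <= 0:
            raise ValueError("a fitted model needs nugget + psill > 0")

    @property
    def sill(self) -> float:
        return self.nugget + self.psill

    def gamma(self, h) -> np.ndarray:
        """Semivariance at lag h (gamma(0) = 0 exactly)."""
        h = np.asarray(h, dtype=float)
        if self.family == "exponential":
            struct = self.psill * (1.0 - np.exp(-h / self.range_m))
        elif self.family == "spherical":
            u = np.clip(h / self.range_m, 0.0, 1.0)
            struct = self.psill * (1.5 * u - 0.5 * u**3)
        else:
            raise ValueError(f"unknown family {self.family!r}")
        return np.where(h > 0, self.nugget + struct, 0.0)

    def covariance(self, h) -> np.ndarray:
        return self.sill - self.gamma(h)


def _default_bins(spacing: float) -> np.ndarray:
    """10 bins of width spacing/2 up to 5 x spacing."""
    return np.arange(0.0, 5.0 * spacing + spacing / 4.0, spacing / 2.0)


def empirical_variogram(
    coords: np.ndarray,
    values: np.ndarray,
    bin_edges: Optional[np.ndarray] = None,
    spacing: float = 500.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Matheron estimator per lag bin: (bin_edges, semivariance, pair_counts)."""
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    if bin_edges is None:
        bin_edges = _default_bins(spacing)
    d = pdist(coords)
    dv = pdist(values[:, None], metric="sqeuclidean")  # (z_i - z_j)^2
    which = np.digitize(d, bin_edges) - 1
    k = len(bin_edges) - 1
    gamma = np.full(k, np.nan)
    counts = np.zeros(k, dtype=int)
    for b in range(k):
        sel = which == b
        counts[b] = int(sel.sum())
        if counts[b] > 0:
            gamma[b] = 0.5 * dv[sel].mean()
    return np.asarray(bin_edges, float), gamma, counts


def _morans_i_per_bin(coords, values, bin_edges):
    z = values - values.mean()
    denom = (z**2).mean()
    d = squareform(pdist(coords))
    k = len(bin_edges) - 1
    corr = np.full(k, np.nan)
    counts = np.zeros(k, dtype=int)
    for b in range(k):
        w = (d > bin_edges[b]) & (d <= bin_edges[b + 1])
        np.fill_diagonal(w, False)
        counts[b] = int(w.sum() // 2)
        sw = w.sum()
        if sw > 0:
            corr[b] = (z @ (w @ z)) / sw / denom
    return corr, counts


def estimate_correlogram(
    coords: np.ndarray,
    values: np.ndarray,
    bin_edges: Optional[np.ndarray] = None,
    estimator: str = "semivariance",
    spacing: float = 500.0,
) -> Correlogram:
    """Empirical spatial correlation per lag-distance class.

    The default route computes the Matheron semivariogram and transforms it
    with ``rho = 1 - gamma / s^2``; bins with fewer than 10 pairs are flagged
    unreliable via :attr:`Correlogram.reliable`.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    if coords.shape[0] < 10:
        raise MudflatError("need at least 10 stations for a correlogram")
    var = float(values.var(ddof=1))
    if var <= 0:
        raise DegenerateFieldError("constant values: autocorrelation undefined")
    if bin_edges is None:
        bin_edges = _default_bins(spacing)
    if estimator == "semivariance":
        edges, gamma, counts = empirical_variogram(coords, values, bin_edges, spacing)
        corr = 1.0 - gamma / var
        return Correlogram(edges, corr, counts, estimator, var, semivariance=gamma)
    if estimator == "morans_i":
        corr, counts = _morans_i_per_bin(coords, values, np.asarray(bin_edges, float))
        return Correlogram(np.asarray(bin_edges, float), corr, counts, estimator, var)
    raise ValueError(f"unknown estimator {estimator!r}")


def fit_variogram(
    data: Union[Correlogram, tuple],
    family: str = "exponential",
    spacing: float = 500.0,
) -> VariogramModel:
    """Weighted-least-squares fit of a parametric variogram.

    ``data`` is a :class:`Correlogram` (the semivariance route), a
    ``(coords, values)`` pair, or an ``(h, gamma, counts)`` triple. Weights
    are the per-bin pair counts. Returns the model with a convergence flag;
    when the fitted structure is negligible relative to the nugget the range
    is flagged unidentifiable.
    """
    if isinstance(data, Correlogram):
        if data.semivariance is None:
            gamma_all = data.sample_variance * (1.0 - data.correlation)
        else:
            gamma_all = data.semivariance
        h_all, counts_all = data.bin_centers, data.pair_counts
        scale = data.sample_variance
    elif isinstance(data, tuple) and len(data) == 2:
        edges, gamma_all, counts_all = empirical_variogram(data[0], data[1], spacing=spacing)
        h_all = 0.5 * (edges[:-1] + edges[1:])
        scale = float(np.asarray(data[1]).var(ddof=1))
    elif isinstance(data, tuple) and len(data) == 3:
        h_all, gamma_all, counts_all = (np.asarray(a, float) for a in data)
        scale = float(np.nanmax(gamma_all))
    else:
        raise TypeError("expected Correlogram, (coords, values) or (h, gamma, counts)")

    usable = (np.asarray(counts_all) > 0) & np.isfinite(gamma_all) & (np.asarray(h_all) > 0)
    if usable.sum() < 3:
        raise MudflatError("need at least 3 usable lag bins to fit a variogram")
    h = np.asarray(h_all, float)[usable]
    g = np.asarray(gamma_all, float)[usable]
    w = np.asarray(counts_all, float)[usable]

    def model(hh, nugget, psill, rng):
        vm = VariogramModel(max(nugget, 0.0), max(psill, 1e-12), max(rng, 1e-6), family)
        return vm.gamma(hh)

    p0 = (max(g[0] * 0.5, 1e-6 * scale), max(scale - g[0] * 0.5, 1e-6 * scale), h.mean() / 2.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                model,
                h,
                g,
                p0=p0,
                sigma=1.0 / np.sqrt(w),
                absolute_sigma=False,
                bounds=([0.0, 0.0, 1e-6], [np.inf, np.inf, 100.0 * h.max()]),
                maxfev=20000,
            )
        converged = True
    except RuntimeError as exc:
        raise MudflatError(f"variogram fit did not converge: {exc}") from None
    nugget, psill, range_m = (float(v) for v in popt)
    identifiable = psill > 1e-3 * max(nugget + psill, 1e-300) and range_m < 50.0 * h.max()
    return VariogramModel(
        nugget, psill, max(range_m, 1e-6), family, converged, identifiable
    )


class OrdinaryKriging(RegressorMixin, BaseEstimator):
    """Ordinary kriging: best linear unbiased interpolation from station data.

    Parameters
    ----------
    variogram : VariogramModel or None
        Spatial-dependence model. If None, an exponential model is estimated
        from the training data at fit time (``spacing`` sets the lag bins).
    spacing : float
        Nominal station spacing (m) used for automatic lag bins.

    Attributes (after fit)
    ----------------------
    variogram_ : VariogramModel — the model actually used.
    X_, y_ : training coordinates and values.

    Weights at every prediction point sum to one (the unbiasedness
    constraint); with a zero nugget the predictor is exact at data points.
    """

    def __init__(self, variogram: Optional[VariogramModel] = None, spacing: float = 500.0):
        self.variogram = variogram
        self.spacing = spacing

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_stations, 2) metric coordinates")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        if X.shape[0] < 2:
            raise ValueError("ordinary kriging needs at least 2 stations")
        self.X_ = X
        self.y_ = y
        if self.variogram is None:
            self.variogram_ = fit_variogram(
                estimate_correlogram(X, y, spacing=self.spacing), spacing=self.spacing
            )
        else:
            self.variogram_ = self.variogram
        n = X.shape[0]
        K = np.empty((n + 1, n + 1))
        K[:n, :n] = self.variogram_.gamma(squareform(pdist(X)))
        K[n, :n] = 1.0
        K[:n, n] = 1.0
        K[n, n] = 0.0
        self._K = K
        self._singular = False
        try:
            from scipy.linalg import lu_factor

            self._lu = lu_factor(K)
        except Exception:
            self._singular = True
            warnings.warn(
                "singular kriging system; falling back to nearest-neighbour",
                RuntimeWarning,
            )
        return self

    def kriging_weights(self, X) -> np.ndarray:
        """(m, n) weights; each row sums to 1."""
        check_is_fitted(self, "X_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n = self.X_.shape[0]
        rhs = np.empty((n + 1, X.shape[0]))
        rhs[:n, :] = self.variogram_.gamma(cdist(self.X_, X))
        rhs[n, :] = 1.0
        from scipy.linalg import lu_solve

        sol = lu_solve(self._lu, rhs)
        return sol[:n, :].T

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "X_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self._singular:
            nearest = cdist(X, self.X_).argmin(axis=1)
            return self.y_[nearest]
        return self.kriging_weights(X) @ self.y_


def interpolate(
    coords: np.ndarray,
    values: np.ndarray,
    model: VariogramModel,
    resolution: float = 25.0,
    extent: Optional[tuple[float, float, float, float]] = None,
) -> tuple[Raster, Raster]:
    """Krige station values onto a regular grid.

    Returns ``(surface, low_confidence)`` rasters; cells farther than three
    ranges from any station are flagged low-confidence. A singular kriging
    system degrades to nearest-neighbour interpolation with a warning.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    if extent is None:
        extent = (
            coords[:, 0].min(), coords[:, 1].min(),
            coords[:, 0].max(), coords[:, 1].max(),
        )
    x0, y0, x1, y1 = extent
    nx = max(int(np.ceil((x1 - x0) / resolution)), 1)
    ny = max(int(np.ceil((y1 - y0) / resolution)), 1)
    xs = x0 + (np.arange(nx) + 0.5) * resolution
    ys = y0 + (np.arange(ny) + 0.5) * resolution
    gx, gy = np.meshgrid(xs, ys)
    targets = np.column_stack([gx.ravel(), gy.ravel()])

    ok = OrdinaryKriging(variogram=model).fit(coords, values)
    pred = ok.predict(targets).reshape(ny, nx)
    dist = cdist(targets, coords).min(axis=1).reshape(ny, nx)
    low_conf = dist > 3.0 * model.range_m
    surface = Raster(pred, resolution, origin=(x0, y0))
    return surface, Raster(low_conf, resolution, origin=(x0, y0))
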