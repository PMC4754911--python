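"""Growth-curve characterisation with P-splines.

Projected leaf area measured several times per day fluctuates with diel
leaf movement on top of the underlying growth trend, so raw differences can
show negative apparent growth.  A P-spline -- a B-spline basis regression
with a difference penalty on adjacent coefficients (Eilers & Marx) --
provides a smooth semiparametric growth curve from which slopes and
relative growth rates are derived; the unsmoothed 3-hourly percentage
change is kept as the leaf-movement statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import solve

__all__ = [
    "TimeSeries",
    "SplineFit",
    "fit_pspline",
    "empirical_slope",
    "relative_growth_rate",
    "percent_change",
]


@dataclass
class TimeSeries:
    """A single plant's trait time series (times in hours since sowing)."""

    times: np.ndarray
    values: np.ndarray
    plant: tuple[int, int, int] | None = None  # (tile, x_within, y_within)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


def _pspline_knots(lo: float, hi: float, n_segments: int, degree: int) -> np.ndarray:
    """Equally spaced B-spline knots extended ``degree`` steps past each end.

    The interior knots come from ``linspace`` so the boundary knots equal
    ``lo``/``hi`` exactly and the data endpoints stay in-bounds.
    """
    interior = np.linspace(lo, hi, n_segments + 1)
    dx = (hi - lo) / n_segments
    left = lo - dx * np.arange(degree, 0, -1)
    right = hi + dx * np.arange(1, degree + 1)
    return np.concatenate([left, interior, right])


@dataclass
class SplineFit:
    """A fitted P-spline growth curve."""

    knot_vector: np.ndarray
    degree: int
    penalty_order: int
    lam: float
    coefficients: np.ndarray
    times: np.ndarray
    fitted: np.ndarray
    gcv: float

    @property
    def knots(self) -> int:
        """Number of interior knots."""
        return len(self.knot_vector) - 2 * (self.degree + 1)

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    def predict(self, times: np.ndarray) -> np.ndarray:
        times = np.atleast_1d(np.asarray(times, dtype=float))
        lo, hi = self.domain
        if np.any(times < lo - 1e-9) or np.any(times > hi + 1e-9):
            raise ValueError(f"requested times outside the fitted range [{lo}, {hi}]")
        times = np.clip(times, lo, hi)
        B = BSpline.design_matrix(times, self.knot_vector, self.degree).toarray()
        return B @ self.coefficients


def _solve_pspline(
    B: np.ndarray, y: np.ndarray, P: np.ndarray, lam: float
) -> tuple[np.ndarray, float, float]:
    """Penalised normal equations; returns (theta, rss, effective dof)."""
    BtB = B.T @ B
    A = BtB + lam * P
    theta = solve(A, B.T @ y, assume_a="pos")
    fitted = B @ theta
    rss = float(np.sum((y - fitted) ** 2))
    # tr(H) = tr(A^-1 B'B)
    ed = float(np.trace(solve(A, BtB, assume_a="pos")))
    return theta, rss, ed


def fit_pspline(
    series: TimeSeries,
    degree: int = 3,
    penalty_order: int = 2,
    lam: float | None = None,
    n_segments: int | None = None,
    lambda_grid: np.ndarray | None = None,
) -> SplineFit:
    """Fit a penalised B-spline to a trait time series.

    Minimises ``||y - B theta||^2 + lam * ||D_d theta||^2`` where ``B`` is a
    cubic B-spline basis on equally spaced knots (one segment per observed
    day, at least 10) and ``D_d`` is the d-th order difference operator on
    the coefficients.  With ``lam=None`` the penalty weight is chosen by
    generalized cross-validation over a log-spaced grid 1e-4..1e8.

    The penalty null space contains polynomials of degree ``penalty_order -
    1``: a second-order penalty leaves straight lines unpenalised, so a
    noiseless linear series is reproduced exactly at any ``lam`` and the
    ``lam -> inf`` limit is the ordinary least-squares line.
    """
    n = len(series)
    if n < degree + 2:
        raise ValueError(f"need at least degree + 2 = {degree + 2} observations, got {n}")
    t, y = series.times, series.values
    if n_segments is None:
        n_days = max(1, len(np.unique(np.floor(t / 24.0))))
        n_segments = max(10, n_days)
    knots = _pspline_knots(t[0], t[-1], n_segments, degree)
    B = BSpline.design_matrix(t, knots, degree).toarray()
    nb = B.shape[1]
    if penalty_order >= nb:
        raise ValueError("penalty_order must be smaller than the basis size")
    D = np.diff(np.eye(nb), n=penalty_order, axis=0)
    P = D.T @ D

    if lam is not None:
        if lam < 0:
            raise ValueError("lam must be >= 0")
        theta, rss, ed = _solve_pspline(B, y, P, lam)
        gcv = n * rss / (n - ed) ** 2 if n > ed else np.inf
        best = (lam, theta, rss, ed, gcv)
    else:
        if lambda_grid is None:
            lambda_grid = np.logspace(-4, 8, 61)
        best = None
        for lam_i in lambda_grid:
            theta, rss, ed = _solve_pspline(B, y, P, lam_i)
            gcv = n * rss / (n - ed) ** 2 if n > ed else np.inf
            if best is None or gcv < best[4]:
                best = (lam_i, theta, rss, ed, gcv)
        assert best is not None

    lam_best, theta, rss, ed, gcv = best
    return SplineFit(
        knot_vector=knots,
        degree=degree,
        penalty_order=penalty_order,
        lam=float(lam_best),
        coefficients=theta,
        times=t.copy(),
        fitted=B @ theta,
        gcv=float(gcv),
    )


def empirical_slope(
    fit: SplineFit, times: np.ndarray, grid_points: int = 2001
) -> np.ndarray:
    """Empirical growth slope (trait units per hour) at the requested times.

    The slope is taken as central finite differences of the fitted curve on
    a fine regular grid spanning the fitted range, then interpolated at the
    requested times.  Times outside the fitted range raise.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    lo, hi = fit.domain
    if np.any(times < lo - 1e-9) or np.any(times > hi + 1e-9):
        raise ValueError(f"requested times outside the fitted range [{lo}, {hi}]")
    grid = np.linspace(lo, hi, grid_points)
    slope = np.gradient(fit.predict(grid), grid)
    return np.interp(np.clip(times, lo, hi), grid, slope)


def relative_growth_rate(fit: SplineFit, times: np.ndarray) -> np.ndarray:
    """Relative growth rate RGR(t) = slope(t) / fitted(t), per hour.

    Requires strictly positive fitted values at the requested times; for an
    exponentially growing plant the RGR is the (constant) exponential rate.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    fitted = fit.predict(times)
    if np.any(fitted <= 0):
        raise ValueError("relative growth rate undefined where the fitted curve is <= 0")
    return empirical_slope(fit, times) / fitted


def percent_change(series: TimeSeries) -> tuple[np.ndarray, np.ndarray]:
    """Step-to-step percentage change, the leaf-movement statistic.

    For consecutive observations the change ``100 * (v[i+1] - v[i]) / v[i]``
    is stamped at the later time.  Entries with a zero denominator are NaN
    (flagged undefined).  Unlike the smoothed slope, this captures the diel
    leaf-angle oscillation and can be negative while the plant is growing.
    """
    if len(series) < 2:
        raise ValueError("percent_change needs at least 2 observations")
    v = series.values
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * np.diff(v) / v[:-1]
    pct[v[:-1] == 0] = np.nan
    return series.times[1:].copy(), pct
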