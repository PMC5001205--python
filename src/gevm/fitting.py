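"""Estimation cascade for the CV-mean variation model.

Three stages, operating in the (log10 mean, log10 CV) plane:

1. ``robust_local_fit`` — locally weighted linear regression with iterative
   bisquare down-weighting of outliers (the locfit.robust recipe), evaluated
   on a uniform grid;
2. ``determine_support`` + ``subsample_curve`` — restrict the curve to the
   region with enough data density, cut it at its smallest-CV point, and
   resample it at a fixed 0.01 log10-mean interval so dense mid-range regions
   do not dominate the next stage;
3. ``fit_gevm`` / ``fit_noise_model`` — bounded nonlinear least squares for
   the two-parameter models.

``cv_difference`` turns the fitted curve into a per-gene statistic: the
signed shortest distance from the gene's point to the model curve (positive
above the curve, i.e. more variable than the population baseline).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Tuple

import numpy as np
from scipy.optimize import least_squares

from .model_core import GEVMParams, NoiseModelParams, model_log10cv, noise_model_log10cv
from .preprocessing import GeneStats

__all__ = [
    "FitError",
    "LocalFitCurve",
    "SubsampledPoints",
    "GevmFitResult",
    "robust_local_fit",
    "determine_support",
    "subsample_curve",
    "fit_gevm",
    "fit_noise_model",
    "cv_difference",
    "estimate_models",
]


class FitError(RuntimeError):
    """Raised when a fitting stage cannot produce a usable result.

    ``best_params`` carries the best parameters found so far when a nonlinear
    solver fails to converge.
    """

    def __init__(self, message: str, best_params=None):
        super().__init__(message)
        self.best_params = best_params


@dataclass
class LocalFitCurve:
    """Smoothed log10 CV as a function of log10 mean on a uniform grid."""

    grid: np.ndarray
    fitted: np.ndarray
    start_pos: Optional[float] = None
    terminal_pos: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.grid) != len(self.fitted):
            raise ValueError("grid and fitted lengths differ")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")

    def __call__(self, x) -> np.ndarray:
        """Interpolate the curve (clamped at the grid ends)."""
        return np.interp(x, self.grid, self.fitted)


@dataclass
class SubsampledPoints:
    """(log10 mean, log10 CV) pairs at a fixed log10-mean interval."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        if len(self.x) != len(self.y):
            raise ValueError("x and y lengths differ")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


def _log_points(stats: GeneStats) -> Tuple[np.ndarray, np.ndarray]:
    """Finite (log10 mean, log10 CV) pairs; genes with CV <= 0 are dropped."""
    ok = (stats.mean > 0) & (stats.cv > 0)
    return np.log10(stats.mean[ok]), np.log10(stats.cv[ok])


def _tricube(u: np.ndarray) -> np.ndarray:
    return np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3


def _local_poly_value(xw: np.ndarray, yw: np.ndarray, w: np.ndarray, degree: int) -> float:
    """Weighted degree-``degree`` polynomial fit of (xw, yw), evaluated at xw = 0."""
    for deg in range(degree, 0, -1):
        X = np.vander(xw, deg + 1, increasing=True)
        XtW = X.T * w
        try:
            coef = np.linalg.solve(XtW @ X, XtW @ yw)
        except np.linalg.LinAlgError:
            continue  # ill-conditioned window; retry with a lower degree
        return float(coef[0])
    sw = w.sum()
    return float((w * yw).sum() / sw)


def robust_local_fit(
    stats: GeneStats,
    span: float = 0.3,
    robust_iters: int = 4,
    degree: int = 2,
    grid_step: float = 0.005,
) -> LocalFitCurve:
    """Robust locally weighted polynomial regression of log10 CV on log10 mean.

    At each grid position a degree-``degree`` polynomial (default quadratic,
    matching locfit's default and keeping the boundary bias of the flattening
    curve small) is fitted over the ``span`` fraction of nearest points,
    weighted by a tricube kernel; ``robust_iters`` reweighting passes apply
    bisquare weights to residuals scaled by six times their median absolute
    value, so isolated outliers are progressively ignored.  The curve is
    evaluated on a uniform grid covering the data.
    """
    x, y = _log_points(stats)
    if len(x) < 50:
        raise FitError("need at least 50 genes with positive mean and CV")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    if xs[-1] - xs[0] <= 0:
        raise FitError("degenerate input: all gene means identical")

    n = len(xs)
    k = max(degree + 1, int(math.ceil(span * n)))
    n_grid = max(51, int(math.ceil((xs[-1] - xs[0]) / grid_step)) + 1)
    grid = np.linspace(xs[0], xs[-1], n_grid)

    robust_w = np.ones(n)
    fitted = np.empty(n_grid)
    for iteration in range(robust_iters + 1):
        for g, x0 in enumerate(grid):
            d = np.abs(xs - x0)
            h = np.partition(d, k - 1)[k - 1]
            if h <= 0:
                h = grid_step  # piled-up duplicates; fall back to one grid step
            lo = np.searchsorted(xs, x0 - h, side="left")
            hi = np.searchsorted(xs, x0 + h, side="right")
            xw = xs[lo:hi] - x0
            w = _tricube(xw / h) * robust_w[lo:hi]
            if w.sum() <= 0:
                fitted[g] = fitted[g - 1] if g else np.median(ys)
                continue
            fitted[g] = _local_poly_value(xw, ys[lo:hi], w, degree)
        if iteration < robust_iters:
            resid = ys - np.interp(xs, grid, fitted)
            s = np.median(np.abs(resid))
            if s <= 0:
                break
            robust_w = np.clip(1.0 - (resid / (6.0 * s)) ** 2, 0.0, None) ** 2
    return LocalFitCurve(grid=grid, fitted=fitted)


def determine_support(
    stats: GeneStats,
    curve: LocalFitCurve,
    density_fraction: float = 0.005,
    window: float = 0.05,
) -> Tuple[float, float]:
    """Locate the usable support of the fitted curve.

    The start is the smallest grid position whose +-``window`` log10-mean
    neighbourhood holds more than ``density_fraction`` of all genes (so the
    sparse low-expression fringe cannot dominate after subsampling); the
    terminal is the (leftmost) grid position where the curve attains its
    minimum log10 CV, beyond which the curve is treated as flat.  Both are
    recorded on ``curve`` and returned.
    """
    x, _ = _log_points(stats)
    xs = np.sort(x)
    n = len(xs)
    counts = np.searchsorted(xs, curve.grid + window, side="right") - np.searchsorted(
        xs, curve.grid - window, side="left"
    )
    dense = counts > density_fraction * n
    if not dense.any():
        raise FitError(
            "no grid position passes the density rule; more genes are needed"
        )
    start_idx = int(np.argmax(dense))
    start_pos = float(curve.grid[start_idx])
    tail = curve.fitted[start_idx:]
    terminal_pos = float(curve.grid[start_idx + int(np.argmin(tail))])
    curve.start_pos, curve.terminal_pos = start_pos, terminal_pos
    return start_pos, terminal_pos


def subsample_curve(curve: LocalFitCurve, interval: float = 0.01) -> SubsampledPoints:
    """Resample the curve at a fixed log10-mean interval over its support."""
    if curve.start_pos is None or curve.terminal_pos is None:
        raise FitError("curve support not determined; call determine_support first")
    span = curve.terminal_pos - curve.start_pos
    n_steps = int(math.floor(span / interval + 1e-9))
    if n_steps < 1:
        raise FitError("curve support is shorter than one subsampling interval")
    xs = curve.start_pos + interval * np.arange(n_steps + 1)
    return SubsampledPoints(x=xs, y=curve(xs))


@dataclass(frozen=True)
class GevmFitResult:
    params: GEVMParams
    converged: bool
    cost: float


def _nls(residual, x0, bounds, restarts, rng_seed=0):
    best = None
    rng = np.random.default_rng(rng_seed)
    for attempt in range(restarts + 1):
        start = np.array(x0, dtype=float)
        if attempt:
            start = start * rng.uniform(0.5, 2.0, size=len(start)) + rng.uniform(
                0, 1e-3, size=len(start)
            )
            start = np.clip(start, [b + 1e-12 for b in bounds[0]], bounds[1])
        try:
            res = least_squares(residual, start, bounds=bounds)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
        if res.success:
            return best
    return best


def fit_gevm(points: SubsampledPoints) -> GevmFitResult:
    """Nonlinear least squares for (alpha, beta) on the subsampled curve.

    Minimizes the squared residuals of ``1/2*log10(beta/mu + alpha)`` with
    alpha >= 0, beta > 0.  Initial values come from the curve's asymptotes:
    CV^2 ~ beta/mu at the left end and CV^2 ~ alpha at the right end.
    """
    if len(points) < 3:
        raise FitError("need at least 3 subsampled points to fit two parameters")
    mu = 10.0 ** points.x
    y = points.y

    def residual(p):
        return y - 0.5 * np.log10(p[1] / mu + p[0])

    alpha0 = min(max(10.0 ** (2 * y[-1]) , 1e-8), 1e6)
    beta0 = min(max(10.0 ** (2 * y[0] + points.x[0]), 1e-6), 1e6)
    res = _nls(residual, [alpha0, beta0], ([0.0, 1e-9], [np.inf, np.inf]), restarts=3)
    if res is None:
        raise FitError("GEVM nonlinear least squares failed")
    params = GEVMParams(alpha=float(res.x[0]), beta=float(res.x[1]))
    if not res.success:
        raise FitError("GEVM fit did not converge", best_params=params)
    return GevmFitResult(params=params, converged=True, cost=float(res.cost))


def fit_noise_model(points: SubsampledPoints) -> NoiseModelParams:
    """Least squares for the comparison model log10(CV) = log10(mu**gamma + delta)."""
    if len(points) < 3:
        raise FitError("need at least 3 subsampled points to fit two parameters")
    mu = 10.0 ** points.x
    y = points.y

    def residual(p):
        inner = np.clip(mu ** p[0] + p[1], 1e-12, None)
        return y - np.log10(inner)

    res = _nls(residual, [-0.5, 0.0], ([-10.0, -1e3], [10.0, 1e3]), restarts=3)
    if res is None or not res.success:
        best = None if res is None else NoiseModelParams(*res.x)
        raise FitError("noise-model fit did not converge", best_params=best)
    return NoiseModelParams(gamma=float(res.x[0]), delta=float(res.x[1]))


def cv_difference(
    stats: GeneStats,
    params: GEVMParams,
    support: Optional[Tuple[float, float]] = None,
    method: str = "orthogonal",
    grid_step: float = 5e-4,
) -> np.ndarray:
    """Signed shortest distance of each gene to the model curve (the CV difference).

    Computed in the (log10 mean, log10 CV) plane; positive above the curve
    (more variable than baseline), negative below.  With ``alpha == 0`` the
    curve is the straight line ``y = -x/2 + log10(beta)/2`` and the analytic
    point-to-line distance is used; otherwise the squared distance is
    minimized over a dense parameterization of the curve spanning one decade
    beyond the fitted support on each side.  ``method='vertical'`` instead
    returns the vertical offset from the curve, for sensitivity checks.

    Genes with nonpositive mean or CV get NaN.
    """
    ok = (stats.mean > 0) & (stats.cv > 0)
    x = np.log10(stats.mean, where=ok, out=np.full(len(stats), np.nan))
    y = np.log10(stats.cv, where=ok, out=np.full(len(stats), np.nan))
    D = np.full(len(stats), np.nan)

    if support is None:
        lo, hi = np.nanmin(x), np.nanmax(x)
    else:
        lo, hi = support
    if method == "vertical":
        D[ok] = y[ok] - model_log10cv(10.0 ** x[ok], params)
        return D
    if method != "orthogonal":
        raise ValueError(f"unknown method {method!r}")

    if params.alpha == 0:
        # line: x/2 + y - log10(beta)/2 = 0, normal vector (1/2, 1)
        c0 = 0.5 * np.log10(params.beta)
        D[ok] = (0.5 * x[ok] + y[ok] - c0) / math.sqrt(1.25)
        return D

    t = np.arange(lo - 1.0, hi + 1.0 + grid_step, grid_step)
    ct = model_log10cv(10.0 ** t, params)
    xo, yo = x[ok], y[ok]
    sign = np.sign(yo - model_log10cv(10.0 ** xo, params))
    sign[sign == 0] = 1.0
    best = np.empty(len(xo), dtype=np.intp)
    chunk = 1024  # bounds the (genes x curve-grid) distance block
    for i in range(0, len(xo), chunk):
        dx = xo[i : i + chunk, None] - t[None, :]
        dy = yo[i : i + chunk, None] - ct[None, :]
        best[i : i + chunk] = (dx**2 + dy**2).argmin(axis=1)

    def sqdist(tv):
        return (xo - tv) ** 2 + (yo - model_log10cv(10.0**tv, params)) ** 2

    # parabolic refinement of the grid minimizer (one Newton-on-parabola step)
    t0 = t[best]
    f0 = sqdist(t0)
    fm = sqdist(t0 - grid_step)
    fp = sqdist(t0 + grid_step)
    denom = fm - 2 * f0 + fp
    shift = np.where(denom > 0, 0.5 * grid_step * (fm - fp) / np.where(denom > 0, denom, 1.0), 0.0)
    shift = np.clip(shift, -grid_step, grid_step)
    dist = np.sqrt(np.minimum(f0, sqdist(t0 + shift)))
    D[ok] = sign * dist
    return D


@dataclass
class ModelEstimate:
    """Everything the cascade produces for one dataset."""

    curve: LocalFitCurve
    points: SubsampledPoints
    gevm: GevmFitResult
    noise: Optional[NoiseModelParams]

    @property
    def support(self) -> Tuple[float, float]:
        return self.curve.start_pos, self.curve.terminal_pos


def estimate_models(
    stats: GeneStats,
    span: float = 0.3,
    robust_iters: int = 4,
    degree: int = 2,
    interval: float = 0.01,
    density_fraction: float = 0.005,
    window: float = 0.05,
    fit_noise: bool = True,
) -> ModelEstimate:
    """Run the full cascade: local fit, support, subsample, both model fits."""
    curve = robust_local_fit(stats, span=span, robust_iters=robust_iters, degree=degree)
    determine_support(stats, curve, density_fraction=density_fraction, window=window)
    points = subsample_curve(curve, interval=interval)
    gevm = fit_gevm(points)
    noise = None
    if fit_noise:
        try:
            noise = fit_noise_model(points)
        except FitError as exc:
            noise = exc.best_params
    return ModelEstimate(curve=curve, points=points, gevm=gevm, noise=noise)
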