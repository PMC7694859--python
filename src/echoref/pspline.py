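"""Penalized B-spline (P-spline) smoothing and linearity diagnostics.

A cubic B-spline basis on equally spaced knots with a second-order
difference penalty on adjacent coefficients; the smoothing parameter is
chosen by generalized cross-validation over a log-spaced grid.  With a
second-order penalty the null space (lambda -> infinity) is a straight
line, which makes the smoother a natural linearity diagnostic: fit the
measurement against BW**b and compare the data-driven smooth with the
straight line the allometric model implies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from .allometry import AllometricFit, fit_allometric, prediction_interval
from .cohort import Cohort, VARIABLE_COLUMNS

DEFAULT_N_KNOTS = 20  # interior knots
DEFAULT_LAMBDA_GRID = tuple(np.logspace(-4, 6, 31))
DEFAULT_LINEARITY_THRESHOLD = 0.02

_DEGREE = 3
_PENALTY_ORDER = 2


def _knot_vector(xl: float, xr: float, n_interior: int) -> np.ndarray:
    """Equally spaced knots with degree-many boundary repeats outside."""
    dx = (xr - xl) / (n_interior + 1)
    return xl + dx * np.arange(-_DEGREE, n_interior + _DEGREE + 2)


def _basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    return BSpline.design_matrix(x, knots, _DEGREE, extrapolate=True).toarray()


@dataclass
class SmoothFit:
    """A fitted penalized spline y = B(x) @ coefficients."""

    knots: np.ndarray
    coefficients: np.ndarray
    lam: float
    edf: float
    gcv: float
    x_range: tuple
    basis_order: int = _DEGREE
    penalty_order: int = _PENALTY_ORDER
    gcv_path: dict = field(default_factory=dict)  # lambda -> gcv on the grid

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return _basis(x, self.knots) @ self.coefficients


def _solve(B, y, DtD, lam):
    coef = np.linalg.solve(B.T @ B + lam * DtD, B.T @ y)
    return coef


def fit_pspline(
    x,
    y,
    n_knots: int = DEFAULT_N_KNOTS,
    lam: float | None = None,
    lambda_grid=DEFAULT_LAMBDA_GRID,
) -> SmoothFit:
    """Fit a cubic P-spline with second-order difference penalty.

    If ``lam`` is None, it is chosen by minimizing GCV(lambda) =
    n * RSS / (n - edf)^2 over ``lambda_grid`` (ties -> smaller lambda).
    ``edf`` is the trace of the smoother matrix.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite input")
    n = x.size
    n_basis = n_knots + _DEGREE + 1
    if n < n_basis:
        raise ValueError(f"need >= {n_basis} points for {n_knots} knots, got {n}")
    xl, xr = float(x.min()), float(x.max())
    if xr <= xl:
        raise ValueError("degenerate predictor: zero range")
    knots = _knot_vector(xl, xr, n_knots)
    B = _basis(x, knots)
    D = np.diff(np.eye(n_basis), n=_PENALTY_ORDER, axis=0)
    DtD = D.T @ D
    BtB = B.T @ B

    def fit_at(l):
        A = BtB + l * DtD
        coef = np.linalg.solve(A, B.T @ y)
        fitted = B @ coef
        rss = float(np.sum((y - fitted) ** 2))
        edf = float(np.trace(np.linalg.solve(A, BtB)))
        gcv = n * rss / (n - edf) ** 2
        return coef, edf, gcv

    path = {}
    if lam is None:
        best = None
        for l in lambda_grid:
            coef, edf, gcv = fit_at(float(l))
            path[float(l)] = gcv
            if best is None or gcv < best[3]:
                best = (float(l), coef, edf, gcv)
        lam_used, coef, edf, gcv = best
    else:
        lam_used = float(lam)
        if lam_used == 0.0:
            coef, *_ = np.linalg.lstsq(B, y, rcond=None)
            fitted = B @ coef
            rss = float(np.sum((y - fitted) ** 2))
            edf = float(np.linalg.matrix_rank(B))
            gcv = n * rss / (n - edf) ** 2 if n > edf else np.inf
        else:
            coef, edf, gcv = fit_at(lam_used)
    return SmoothFit(
        knots=knots,
        coefficients=np.asarray(coef, dtype=float),
        lam=lam_used,
        edf=edf,
        gcv=gcv,
        x_range=(xl, xr),
        gcv_path=path,
    )


@dataclass
class LinearityReport:
    variable: str
    max_rel_dev: float
    edf: float
    threshold: float
    adequate: bool


def linearity_check(
    fit: AllometricFit,
    cohort: Cohort,
    threshold: float = DEFAULT_LINEARITY_THRESHOLD,
    n_knots: int = DEFAULT_N_KNOTS,
) -> LinearityReport:
    """Check that the allometric model's linearity in BW**b holds.

    Fits y = s(BW**b) with a GCV-selected P-spline on the original scale
    and compares the smooth with the OLS straight line in BW**b.  The
    published procedure assessed this by visual inspection of the fitted
    line; here it is operationalized as the maximum |smooth - line|
    relative to the fitted range, evaluated over the central 98% of the
    predictor span, with a 2% adequacy threshold.
    """
    col = VARIABLE_COLUMNS[fit.variable]
    df = cohort.df[["bw_kg", col]].dropna()
    u = df["bw_kg"].to_numpy(dtype=float) ** fit.b
    y = df[col].to_numpy(dtype=float)
    smooth = fit_pspline(u, y, n_knots=n_knots)
    slope, intercept = np.polyfit(u, y, 1)
    lo, hi = np.percentile(u, [1, 99])
    grid = np.linspace(lo, hi, 200)
    s_hat = smooth.predict(grid)
    line = intercept + slope * grid
    frange = float(s_hat.max() - s_hat.min())
    if frange <= 0:
        frange = max(abs(s_hat).max(), 1e-12)
    max_rel_dev = float(np.max(np.abs(s_hat - line)) / frange)
    return LinearityReport(
        variable=fit.variable,
        max_rel_dev=max_rel_dev,
        edf=smooth.edf,
        threshold=threshold,
        adequate=max_rel_dev < threshold,
    )


@dataclass
class GroupComparison:
    variable: str
    mean_upper_diff: float  # mean over the grid of upper_a - upper_b (cm)
    group_effect: float  # additive group effect from the joint smooth model
    grid: np.ndarray
    upper_a: np.ndarray
    upper_b: np.ndarray


def group_upper_limit_difference(
    cohort_a: Cohort,
    cohort_b: Cohort,
    variable: str,
    bw_grid,
    n_knots: int = DEFAULT_N_KNOTS,
) -> GroupComparison:
    """Mean difference between two groups' upper 95% PI limits.

    Fits the allometric model separately per group, evaluates the exact
    upper PI limit on ``bw_grid`` and averages the difference (group a
    minus group b).  A companion joint additive model — group indicator
    plus a shared P-spline in BW — supplies an effect estimate free of
    the allometric functional form.  No p-value is reported.
    """
    grid = np.asarray(list(bw_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty body-weight grid")
    fits = []
    uppers = []
    for coh in (cohort_a, cohort_b):
        if len(coh) == 0:
            raise ValueError("empty cohort")
        f = fit_allometric(coh, variable)
        pis = prediction_interval(f, grid, method="exact")
        uppers.append(np.array([p.upper for p in pis]))
        fits.append(f)

    # Joint additive model: y = alpha * 1[group a] + s(BW).
    col = VARIABLE_COLUMNS[variable]
    frames = []
    for g, coh in ((1.0, cohort_a), (0.0, cohort_b)):
        df = coh.df[["bw_kg", col]].dropna()
        frames.append((g, df["bw_kg"].to_numpy(float), df[col].to_numpy(float)))
    x = np.concatenate([f[1] for f in frames])
    y = np.concatenate([f[2] for f in frames])
    g = np.concatenate([np.full(f[1].shape, f[0]) for f in frames])
    knots = _knot_vector(float(x.min()), float(x.max()), n_knots)
    B = _basis(x, knots)
    n_basis = B.shape[1]
    D = np.diff(np.eye(n_basis), n=_PENALTY_ORDER, axis=0)
    X = np.column_stack([g, B])
    pen = np.zeros((n_basis + 1, n_basis + 1))
    pen[1:, 1:] = D.T @ D
    best = None
    for lam in DEFAULT_LAMBDA_GRID:
        A = X.T @ X + lam * pen
        coef = np.linalg.solve(A, X.T @ y)
        rss = float(np.sum((y - X @ coef) ** 2))
        edf = float(np.trace(np.linalg.solve(A, X.T @ X)))
        gcv = x.size * rss / (x.size - edf) ** 2
        if best is None or gcv < best[0]:
            best = (gcv, coef)
    group_effect = float(best[1][0])

    return GroupComparison(
        variable=variable,
        mean_upper_diff=float(np.mean(uppers[0] - uppers[1])),
        group_effect=group_effect,
        grid=grid,
        upper_a=uppers[0],
        upper_b=uppers[1],
    )
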