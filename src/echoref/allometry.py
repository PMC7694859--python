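"""Allometric scaling fits and body-weight-dependent prediction intervals.

The core model: a dimensional echocardiographic measurement Y (cm) scales
with body weight as Y = a * BW**b, fitted by ordinary least squares on the
log-log scale.  95% prediction intervals come in two flavours:

* ``exact`` — the regression PI with the leverage term,
  log Y_hat +/- t * sigma * sqrt(1 + 1/n + (log BW - xbar)^2 / Sxx),
  back-transformed;
* ``approx`` — the field's on-the-spot formula, log Y_hat +/- t * sigma
  back-transformed, i.e. constants a*exp(-t*sigma) and a*exp(+t*sigma)
  multiplied by BW**b.  At screening-database sample sizes the two differ
  by well under 1%.

Percentile indexing constants are empirical percentiles of the index
Y / BW**b; multiplied by BW**b they reconstruct that percentile curve.
Variables with essentially no weight dependence (fractional shortening)
fall back to a weight-independent percentile cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, FS_COLUMN, VARIABLE_COLUMNS

DEFAULT_PI_LEVEL = 0.95
DEFAULT_PERCENTILES = (2.5, 5.0, 25.0, 50.0, 75.0, 95.0, 97.5)

#: Below this R-squared the weight effect is considered negligible and a
#: weight-independent percentile cutoff is reported instead of a fit.
DEFAULT_R2_GATE = 0.10


def _column(variable: str) -> str:
    if variable == "FS":
        return FS_COLUMN
    try:
        return VARIABLE_COLUMNS[variable]
    except KeyError:
        raise KeyError(f"unknown variable {variable!r}") from None


@dataclass
class AllometricFit:
    """OLS fit of log Y = log a + b log BW with PI bookkeeping."""

    variable: str
    a: float
    b: float
    sigma: float  # residual SD on the log scale, df = n - 2
    n: int
    r2: float
    xbar_log: float  # mean of log BW in the fitting sample
    sxx_log: float  # centered sum of squares of log BW
    t_crit: float  # two-sided Student-t quantile at the PI level, df n-2
    level: float = DEFAULT_PI_LEVEL


@dataclass
class IndexConstants:
    """Percentile -> indexing constant map plus the scaling exponent."""

    variable: str
    exponent: float
    constants: dict  # percentile (0..100) -> constant, nondecreasing

    def __post_init__(self) -> None:
        pcts = sorted(self.constants)
        vals = [self.constants[p] for p in pcts]
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ValueError(
                f"{self.variable}: constants must be nondecreasing in percentile"
            )


@dataclass
class PIResult:
    bw_kg: float
    mean: float
    lower: float
    upper: float
    level: float
    method: str  # "exact" or "approx"


def fit_allometric(
    cohort: Cohort, variable: str, level: float = DEFAULT_PI_LEVEL
) -> AllometricFit:
    """Fit Y = a * BW**b by OLS on the natural-log scale.

    Needs at least 3 complete records (sigma has n-2 degrees of freedom).
    """
    col = _column(variable)
    df = cohort.df[["bw_kg", col]].dropna()
    n = len(df)
    if n < 3:
        raise ValueError(f"{variable}: need >=3 complete records, got {n}")
    x = np.log(df["bw_kg"].to_numpy(dtype=float))
    y = np.log(df[col].to_numpy(dtype=float))
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx <= 0:
        raise ValueError(f"{variable}: zero body-weight variance")
    slope, intercept, r, _, _ = stats.linregress(x, y)
    resid = y - (intercept + slope * x)
    sigma = float(np.sqrt(np.sum(resid**2) / (n - 2)))
    t_crit = float(stats.t.ppf(0.5 + level / 2, df=n - 2))
    return AllometricFit(
        variable=variable,
        a=float(np.exp(intercept)),
        b=float(slope),
        sigma=sigma,
        n=n,
        r2=float(r**2),
        xbar_log=float(x.mean()),
        sxx_log=sxx,
        t_crit=t_crit,
        level=level,
    )


def predict_mean(fit: AllometricFit, bw_kg) -> float | np.ndarray:
    """Mean curve a * BW**b (cm)."""
    bw = np.asarray(bw_kg, dtype=float)
    if np.any(bw <= 0):
        raise ValueError("body weight must be positive")
    out = fit.a * bw**fit.b
    return float(out) if np.isscalar(bw_kg) else out


def prediction_interval(
    fit: AllometricFit, bw_kg, method: str = "exact"
) -> PIResult | list:
    """Back-transformed prediction interval at the given body weight(s).

    ``exact`` uses the full regression PI with the leverage term;
    ``approx`` drops it, giving the constant-based on-the-spot interval.
    """
    scalar = np.isscalar(bw_kg)
    bw = np.atleast_1d(np.asarray(bw_kg, dtype=float))
    if np.any(bw <= 0):
        raise ValueError("body weight must be positive")
    center = np.log(fit.a) + fit.b * np.log(bw)
    if method == "approx":
        half = fit.t_crit * fit.sigma * np.ones_like(bw)
    elif method == "exact":
        lever = 1.0 + 1.0 / fit.n + (np.log(bw) - fit.xbar_log) ** 2 / fit.sxx_log
        half = fit.t_crit * fit.sigma * np.sqrt(lever)
    else:
        raise ValueError(f"unknown PI method {method!r}")
    results = [
        PIResult(
            bw_kg=float(w),
            mean=float(np.exp(c)),
            lower=float(np.exp(c - h)),
            upper=float(np.exp(c + h)),
            level=fit.level,
            method=method,
        )
        for w, c, h in zip(bw, center, half)
    ]
    return results[0] if scalar else results


def pi_from_constants(
    constants: IndexConstants, bw_kg: float, level: float = DEFAULT_PI_LEVEL
) -> PIResult:
    """Percentile-constant prediction interval c_p * BW**b.

    Uses the (2.5, 50, 97.5) constants for a 95% interval (or the matching
    symmetric pair for another level).
    """
    lo_p = round(100 * (1 - level) / 2, 6)
    hi_p = round(100 - lo_p, 6)
    for p in (lo_p, 50.0, hi_p):
        if p not in constants.constants:
            raise KeyError(f"constant at percentile {p} not available")
    if bw_kg <= 0:
        raise ValueError("body weight must be positive")
    scale = bw_kg**constants.exponent
    return PIResult(
        bw_kg=float(bw_kg),
        mean=float(constants.constants[50.0] * scale),
        lower=float(constants.constants[lo_p] * scale),
        upper=float(constants.constants[hi_p] * scale),
        level=level,
        method="approx",
    )


def index_constants(
    fit: AllometricFit,
    cohort: Cohort,
    percentiles=DEFAULT_PERCENTILES,
    parametric: bool = False,
) -> IndexConstants:
    """Indexing constants: percentiles of the index Y / BW**b.

    Empirical percentiles use linear interpolation (same convention as the
    outlier fences).  ``parametric=True`` instead returns the lognormal-
    theory constants a * exp(z_p * sigma); the two agree when the log
    residuals are normal.
    """
    for p in percentiles:
        if not 0 < p < 100:
            raise ValueError(f"percentile {p} outside (0, 100)")
    if parametric:
        consts = {
            float(p): float(fit.a * np.exp(stats.norm.ppf(p / 100) * fit.sigma))
            for p in percentiles
        }
        return IndexConstants(fit.variable, fit.b, consts)
    col = _column(fit.variable)
    df = cohort.df[["bw_kg", col]].dropna()
    if len(df) == 0:
        raise ValueError("empty cohort")
    index = df[col].to_numpy(dtype=float) / df["bw_kg"].to_numpy(dtype=float) ** fit.b
    consts = {float(p): float(np.percentile(index, p)) for p in percentiles}
    return IndexConstants(fit.variable, fit.b, consts)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding, as used in printed reference tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pi_table(
    source,
    bw_grid,
    level: float = DEFAULT_PI_LEVEL,
    ndigits: int = 1,
) -> pd.DataFrame:
    """Reference table: mean and PI bounds per body weight, rounded.

    ``source`` is an :class:`AllometricFit` (approx PI) or
    :class:`IndexConstants`.  One row per BW with columns
    mean/lower/upper plus a formatted "mean (lower-upper)" string.
    """
    grid = list(bw_grid)
    if not grid:
        raise ValueError("empty body-weight grid")
    rows = []
    for bw in grid:
        if isinstance(source, IndexConstants):
            pi = pi_from_constants(source, bw, level=level)
        else:
            pi = prediction_interval(source, bw, method="approx")
        mean = round_half_up(pi.mean, ndigits)
        lower = round_half_up(pi.lower, ndigits)
        upper = round_half_up(pi.upper, ndigits)
        rows.append(
            {
                "bw_kg": bw,
                "mean": mean,
                "lower": lower,
                "upper": upper,
                "formatted": f"{mean:.{ndigits}f} ({lower:.{ndigits}f}-{upper:.{ndigits}f})",
            }
        )
    return pd.DataFrame(rows)


@dataclass
class WeightIndependentCutoff:
    variable: str
    percentile: float
    cutoff: float
    r2: float
    n: int


def weight_independent_cutoff(
    cohort: Cohort,
    variable: str,
    percentile: float = 5.0,
    r2_gate: float = DEFAULT_R2_GATE,
):
    """Cutoff for variables with no meaningful weight dependence.

    Fits the allometric model first; if R^2 < ``r2_gate`` the weight
    effect is negligible (fractional shortening: R^2 ~ 0.04) and the
    empirical ``percentile`` of the raw values is returned as a
    :class:`WeightIndependentCutoff`.  Otherwise the fit itself is
    returned and weight-dependent intervals should be used.
    """
    col = _column(variable)
    vals = cohort.df[col].dropna()
    if len(vals) < 20:
        raise ValueError(f"{variable}: need >=20 records, got {len(vals)}")
    fit = fit_allometric(cohort, variable)
    if fit.r2 >= r2_gate:
        return fit
    return WeightIndependentCutoff(
        variable=variable,
        percentile=float(percentile),
        cutoff=float(np.percentile(vals.to_numpy(dtype=float), percentile)),
        r2=fit.r2,
        n=len(vals),
    )
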