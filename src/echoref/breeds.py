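"""Breed-deviance classification against population prediction intervals.

A breed is deviant for a variable if more than 10.0% of that breed's
measurements fall above, or more than 10.0% below, the population 95%
prediction interval evaluated at each dog's own body weight.  The PIs are
the all-nonsighthound fits, applied to every breed including sighthounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .allometry import (
    AllometricFit,
    IndexConstants,
    pi_from_constants,
    prediction_interval,
)
from .cohort import Cohort, VARIABLE_COLUMNS

DEFAULT_DEVIANCE_CUTOFF_PCT = 10.0


@dataclass
class BreedDevianceRow:
    breed: str
    n: int
    sighthound: bool
    #: per variable: {"pct_above": float, "pct_below": float,
    #:               "above_deviant": bool, "below_deviant": bool, "n": int}
    per_variable: dict

    def deviant_any(self) -> bool:
        return any(
            v["above_deviant"] or v["below_deviant"]
            for v in self.per_variable.values()
        )


def _bounds(fit_or_constants, bw: np.ndarray):
    if isinstance(fit_or_constants, IndexConstants):
        pis = [pi_from_constants(fit_or_constants, w) for w in bw]
    else:
        pis = prediction_interval(fit_or_constants, bw, method="exact")
    return (
        np.array([p.lower for p in pis]),
        np.array([p.upper for p in pis]),
    )


def breed_deviance(
    cohort: Cohort,
    fits: dict,
    cutoff_pct: float = DEFAULT_DEVIANCE_CUTOFF_PCT,
) -> list[BreedDevianceRow]:
    """Fraction of each breed's measurements outside the population PIs.

    ``fits`` maps variable name to an :class:`AllometricFit` (exact PI at
    each dog's BW) or :class:`IndexConstants` (constant-based PI).
    Exceedance is strict (> upper, < lower) against the unrounded bound;
    dogs missing a measurement are excluded from that variable's
    denominator.  Percentages are rounded to 1 decimal; the deviant flag
    per side is strict (pct > cutoff).
    """
    rows = []
    for breed, sub in cohort.df.groupby("breed", sort=True):
        per_var = {}
        for var, fit in fits.items():
            col = VARIABLE_COLUMNS[var]
            d = sub[["bw_kg", col]].dropna()
            if len(d) == 0:
                per_var[var] = {
                    "pct_above": np.nan, "pct_below": np.nan,
                    "above_deviant": False, "below_deviant": False, "n": 0,
                }
                continue
            bw = d["bw_kg"].to_numpy(float)
            y = d[col].to_numpy(float)
            lower, upper = _bounds(fit, bw)
            pct_above = round(100.0 * np.mean(y > upper), 1)
            pct_below = round(100.0 * np.mean(y < lower), 1)
            per_var[var] = {
                "pct_above": pct_above,
                "pct_below": pct_below,
                "above_deviant": bool(pct_above > cutoff_pct),
                "below_deviant": bool(pct_below > cutoff_pct),
                "n": int(len(d)),
            }
        rows.append(
            BreedDevianceRow(
                breed=breed,
                n=int(len(sub)),
                sighthound=bool(sub["sighthound"].iloc[0]),
                per_variable=per_var,
            )
        )
    return rows


def deviance_table(rows: list[BreedDevianceRow]) -> pd.DataFrame:
    """Flatten deviance rows into the published table layout.

    One row per breed (sighthounds asterisked), paired up/down percentage
    columns per variable; dashes for zero exceedance.
    """
    records = []
    for r in rows:
        rec = {"breed": r.breed + ("*" if r.sighthound else ""), "n": r.n}
        for var, v in r.per_variable.items():
            for side, key in (("up", "pct_above"), ("down", "pct_below")):
                val = v[key]
                rec[f"{var}_{side}_pct"] = (
                    "-" if (not np.isfinite(val) or val == 0) else f"{val:.1f}"
                )
        records.append(rec)
    return pd.DataFrame(records)
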