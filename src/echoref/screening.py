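"""Outlier screening with Tukey-style quartile fences.

Values outside "quartile -/+ k * interquartile range" (k = 3, the far-out
fence) are flagged, per breed stratum, with dimensional variables screened
on the natural-log scale.  Flagged measurements are set missing; the dog is
kept for its remaining variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort, FS_COLUMN, VARIABLES, VARIABLE_COLUMNS

#: Breeds with fewer dogs than this are pooled into one screening stratum.
DEFAULT_MIN_STRATUM_N = 50

#: Fence multiplier: quartile +/- k * IQR.
DEFAULT_FENCE_K = 3.0

POOLED_STRATUM = "(pooled small breeds)"


def quartile_fences(values, k: float = DEFAULT_FENCE_K):
    """Tukey fences (Q1 - k*IQR, Q3 + k*IQR).

    Quartiles use linear interpolation between order statistics (the
    widespread "type 7" convention, numpy's default).  Requires at least
    four finite values.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        raise ValueError(f"need at least 4 values, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite input to quartile_fences")
    q1, q3 = np.percentile(arr, [25, 75])
    iqr = q3 - q1
    return float(q1 - k * iqr), float(q3 + k * iqr)


@dataclass
class StratumFences:
    variable: str
    stratum: str
    fence_low: float
    fence_high: float
    scale: str  # "log" for dimensions, "raw" for FS
    flagged_ids: list = field(default_factory=list)


@dataclass
class OutlierReport:
    """Per variable x breed-stratum fences and the flagged record ids."""

    strata: list = field(default_factory=list)
    total_removed: int = 0
    k: float = DEFAULT_FENCE_K
    min_stratum_n: int = DEFAULT_MIN_STRATUM_N

    def flagged(self, variable: str | None = None) -> set:
        out = set()
        for s in self.strata:
            if variable is None or s.variable == variable:
                out.update(s.flagged_ids)
        return out

    def summary(self) -> str:
        lines = [
            f"outlier screen: k={self.k}, min stratum n={self.min_stratum_n}, "
            f"{self.total_removed} measurements removed"
        ]
        for s in self.strata:
            if s.flagged_ids:
                lines.append(
                    f"  {s.variable} / {s.stratum}: {len(s.flagged_ids)} flagged "
                    f"(fences {s.fence_low:.4g}..{s.fence_high:.4g} on {s.scale} scale)"
                )
        return "\n".join(lines)


def screen_cohort(
    cohort: Cohort,
    min_stratum_n: int = DEFAULT_MIN_STRATUM_N,
    k: float = DEFAULT_FENCE_K,
    screen_fs: bool = True,
) -> tuple[Cohort, OutlierReport]:
    """Fence-screen every variable separately within breed strata.

    Strata are breeds with at least ``min_stratum_n`` dogs; all smaller
    breeds are pooled into one stratum so no record goes unscreened.
    Dimensions are screened on the natural-log scale (they are modeled
    multiplicatively); FS is screened untransformed.  Flagged values are
    set missing in the returned cohort copy.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    df = cohort.df.copy()
    counts = df["breed"].value_counts()
    big = set(counts[counts >= min_stratum_n].index)
    stratum = df["breed"].where(df["breed"].isin(big), POOLED_STRATUM)

    report = OutlierReport(k=k, min_stratum_n=min_stratum_n)
    targets = [(var, VARIABLE_COLUMNS[var], "log") for var in VARIABLES]
    if screen_fs:
        targets.append(("FS", FS_COLUMN, "raw"))

    for var, col, scale in targets:
        for name in sorted(stratum.unique()):
            in_stratum = stratum == name
            vals = df.loc[in_stratum, col]
            present = vals.notna()
            if present.sum() < 4:
                continue
            x = vals[present].to_numpy(dtype=float)
            x_scr = np.log(x) if scale == "log" else x
            lo, hi = quartile_fences(x_scr, k=k)
            outside = (x_scr < lo) | (x_scr > hi)
            idx = vals[present].index[outside]
            if len(idx):
                ids = df.loc[idx, "dog_id"].tolist()
                df.loc[idx, col] = np.nan
                report.total_removed += len(idx)
            else:
                ids = []
            report.strata.append(
                StratumFences(
                    variable=var, stratum=name,
                    fence_low=lo, fence_high=hi, scale=scale,
                    flagged_ids=ids,
                )
            )

    screened = Cohort(df, {**cohort.provenance, "screened": True})
    return screened, report
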