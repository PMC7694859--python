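"""Cohort container and record-level validation.

A cohort is one row per screened dog: signalment (breed, sex, age), body
weight in kg, the examiner who measured it, health classification, and up
to six M-mode left-ventricular dimensions in cm (chamber diameters LVDd /
LVDs, septal thicknesses IVSd / IVSs, free-wall thicknesses LVWd / LVWs)
plus fractional shortening in percent.  Units are fixed — kg, cm, %, years
— and never auto-converted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Analysis variables, keyed by their conventional echocardiographic names.
VARIABLES = ("LVDd", "LVDs", "IVSd", "IVSs", "LVWd", "LVWs")

#: Column name in the cohort table for each dimensional variable (cm).
VARIABLE_COLUMNS = {
    "LVDd": "lvdd_cm",
    "LVDs": "lvds_cm",
    "IVSd": "ivsd_cm",
    "IVSs": "ivss_cm",
    "LVWd": "lvwd_cm",
    "LVWs": "lvws_cm",
}

FS_COLUMN = "fs_pct"

REQUIRED_COLUMNS = (
    "dog_id",
    "breed",
    "sex",
    "age_years",
    "bw_kg",
    "examiner_id",
    "sighthound",
    "health_class",
    "view",
    *VARIABLE_COLUMNS.values(),
    FS_COLUMN,
)

SEX_VALUES = frozenset({"male", "female"})
HEALTH_VALUES = frozenset({"all_ok", "immaculate", "excluded"})
VIEW_VALUES = frozenset({"long_axis", "short_axis"})

#: Tolerance (percentage points) for FS == 100*(LVDd-LVDs)/LVDd; source FS
#: was machine-computed then rounded, so exact equality is unachievable.
FS_TOLERANCE = 0.5


class CohortValidationError(ValueError):
    """A record violates a cohort invariant (strict mode)."""


@dataclass
class Cohort:
    """An ordered collection of screened dogs.

    Parameters
    ----------
    df :
        One row per dog with the columns in :data:`REQUIRED_COLUMNS`.
    provenance :
        Free-text metadata (source file, generator seed, config hash).
    """

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise CohortValidationError(f"missing required columns: {missing}")
        if self.df["dog_id"].duplicated().any():
            dupes = self.df.loc[self.df["dog_id"].duplicated(), "dog_id"]
            raise CohortValidationError(
                f"dog_id not unique: {sorted(set(dupes))[:5]}"
            )

    def __len__(self) -> int:
        return len(self.df)

    # -- analysis-group helpers -------------------------------------------

    def healthy(self) -> "Cohort":
        """Dogs not excluded on health grounds."""
        return Cohort(
            self.df[self.df["health_class"] != "excluded"].reset_index(drop=True),
            dict(self.provenance),
        )

    def nonsighthound(self) -> "Cohort":
        """The *all nonsighthound* analysis group."""
        keep = (~self.df["sighthound"].astype(bool)) & (
            self.df["health_class"] != "excluded"
        )
        return Cohort(self.df[keep].reset_index(drop=True), dict(self.provenance))

    def immaculate(self) -> "Cohort":
        """The stricter *immaculate nonsighthound* group (subset of above)."""
        keep = (~self.df["sighthound"].astype(bool)) & (
            self.df["health_class"] == "immaculate"
        )
        return Cohort(self.df[keep].reset_index(drop=True), dict(self.provenance))

    def copy(self) -> "Cohort":
        return Cohort(self.df.copy(), dict(self.provenance))


def validate_frame(df: pd.DataFrame, strict: bool = True):
    """Validate cohort rows against the record invariants.

    Returns ``(clean_df, problems)`` where *problems* is a list of
    human-readable strings, one per violation.  In strict mode the first
    violation raises :class:`CohortValidationError` naming the row and
    field; in lenient mode violating rows are dropped.
    """
    problems: list[str] = []
    bad = np.zeros(len(df), dtype=bool)

    def flag(mask: np.ndarray, message: str) -> None:
        for idx in np.flatnonzero(mask):
            problems.append(f"row {idx}: {message}")
        bad[mask] = True

    bw = pd.to_numeric(df["bw_kg"], errors="coerce")
    flag((~np.isfinite(bw)) | (bw <= 0), "field bw_kg must be a positive number")

    for var, col in VARIABLE_COLUMNS.items():
        vals = pd.to_numeric(df[col], errors="coerce")
        present = df[col].notna()
        flag(
            present.to_numpy() & ((~np.isfinite(vals)) | (vals <= 0)).to_numpy(),
            f"field {col} must be positive when present",
        )

    fs = pd.to_numeric(df[FS_COLUMN], errors="coerce")
    fs_present = df[FS_COLUMN].notna().to_numpy()
    flag(
        fs_present & ((~np.isfinite(fs)) | (fs <= 0) | (fs >= 100)).to_numpy(),
        f"field {FS_COLUMN} must lie in (0, 100) when present",
    )

    # FS must agree with 100*(LVDd-LVDs)/LVDd to within rounding.
    lvdd = pd.to_numeric(df["lvdd_cm"], errors="coerce").to_numpy()
    lvds = pd.to_numeric(df["lvds_cm"], errors="coerce").to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        implied = 100.0 * (lvdd - lvds) / lvdd
    checkable = fs_present & np.isfinite(implied) & np.isfinite(fs.to_numpy())
    flag(
        checkable & (np.abs(fs.to_numpy() - implied) > FS_TOLERANCE),
        f"field {FS_COLUMN} inconsistent with 100*(LVDd-LVDs)/LVDd",
    )

    for colname, allowed in (
        ("sex", SEX_VALUES),
        ("health_class", HEALTH_VALUES),
        ("view", VIEW_VALUES),
    ):
        flag(
            (~df[colname].isin(allowed)).to_numpy(),
            f"field {colname} must be one of {sorted(allowed)}",
        )

    if strict and problems:
        raise CohortValidationError(problems[0])
    return df[~bad].reset_index(drop=True), problems
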