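"""Reading and writing cohort tables and fitted-model files.

Cohorts travel as CSV with a fixed header (missing values as empty cells);
fitted models and report tables are self-describing JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path

import pandas as pd

from .cohort import (
    REQUIRED_COLUMNS,
    Cohort,
    CohortValidationError,
    validate_frame,
)

log = logging.getLogger(__name__)

_NUMERIC = [
    "age_years",
    "bw_kg",
    "lvdd_cm",
    "lvds_cm",
    "ivsd_cm",
    "ivss_cm",
    "lvwd_cm",
    "lvws_cm",
    "fs_pct",
]


def read_cohort(path, strict: bool = True) -> Cohort:
    """Read a cohort CSV, validating every record.

    In strict mode any invariant violation (nonpositive weight or
    dimension, FS inconsistent with the chamber diameters, unknown
    category) raises :class:`CohortValidationError` naming the row and
    field.  In lenient mode violating records are dropped and counted in
    a log summary.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"dog_id": str, "examiner_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"missing required columns: {missing}")
    if strict:
        for col in _NUMERIC:
            coerced = pd.to_numeric(df[col], errors="coerce")
            nonnum = df[col].notna() & coerced.isna()
            if nonnum.any():
                row = int(nonnum.idxmax())
                raise CohortValidationError(
                    f"row {row}: field {col} is not numeric: {df.loc[row, col]!r}"
                )
    for col in _NUMERIC:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["sighthound"] = df["sighthound"].astype(bool)
    clean, problems = validate_frame(df, strict=strict)
    if problems:
        log.warning(
            "dropped %d invalid records reading %s (first: %s)",
            len(df) - len(clean),
            path,
            problems[0],
        )
    return Cohort(clean, {"source": str(path), "n_dropped": len(df) - len(clean)})


def write_cohort(cohort: Cohort, path) -> Path:
    """Write a cohort to CSV (missing values as empty cells)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.df.to_csv(path, index=False)
    return path


def _check_finite(obj: dict, context: str) -> None:
    for key, value in obj.items():
        if isinstance(value, dict):
            _check_finite(value, f"{context}.{key}")
        elif isinstance(value, (list, tuple)):
            for i, v in enumerate(value):
                if isinstance(v, float) and not math.isfinite(v):
                    raise ValueError(f"non-finite value in {context}.{key}[{i}]")
        elif isinstance(value, float) and not math.isfinite(value):
            raise ValueError(f"non-finite value in {context}.{key}")


def write_model(obj, path) -> Path:
    """Serialize a fitted model or report table to JSON.

    Accepts any of the package's result dataclasses (or a plain dict).
    Refuses non-finite fields: a NaN sigma is a broken fit, not data.
    Read-back via :func:`read_model` reproduces values to full stored
    precision.
    """
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        payload = {"type": type(obj).__name__, **dataclasses.asdict(obj)}
    elif isinstance(obj, dict):
        payload = dict(obj)
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")
    _check_finite(payload, type(obj).__name__)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")
    return path


def read_model(path) -> dict:
    """Read back a JSON model file as a dict (``type`` key names the class)."""
    return json.loads(Path(path).read_text())
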