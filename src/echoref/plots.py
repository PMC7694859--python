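"""Scatter + prediction-band plots (illustrative, no styling contract)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .allometry import AllometricFit, prediction_interval
from .cohort import Cohort, VARIABLE_COLUMNS


def scatter_pi_plot(cohort: Cohort, fit: AllometricFit, path) -> Path:
    """Scatter of a dimension against body weight with mean curve and PI band."""
    col = VARIABLE_COLUMNS[fit.variable]
    df = cohort.df[["bw_kg", col]].dropna()
    bw = df["bw_kg"].to_numpy(float)
    grid = np.linspace(bw.min(), bw.max(), 200)
    pis = prediction_interval(fit, grid, method="exact")
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(bw, df[col], s=4, alpha=0.25, color="steelblue")
    ax.plot(grid, [p.mean for p in pis], color="black", lw=1.5, label="mean")
    ax.plot(grid, [p.lower for p in pis], "--", color="firebrick", lw=1, label="95% PI")
    ax.plot(grid, [p.upper for p in pis], "--", color="firebrick", lw=1)
    ax.set_xlabel("body weight (kg)")
    ax.set_ylabel(f"{fit.variable} (cm)")
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
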