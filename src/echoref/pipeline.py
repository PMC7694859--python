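"""End-to-end reference-interval pipeline.

screen -> fit (all vs immaculate nonsighthound groups) -> linearity
validation -> group comparison -> indexing constants -> PI table -> breed
deviance -> interobserver variance, with every table written to an output
directory.  Fully deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import allometry, breeds as breeds_mod, observer as observer_mod, pspline
from .cohort import Cohort, VARIABLES
from .io import read_cohort, write_cohort
from .reference import PI_TABLE_BW_GRID
from .screening import DEFAULT_FENCE_K, DEFAULT_MIN_STRATUM_N, screen_cohort
from .simulate import SimConfig, default_truth, generate_cohort

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    input_path: str | None = None  # CSV cohort; mutually exclusive with simulate
    simulate: bool = False
    seed: int = 0
    variables: tuple = VARIABLES
    bw_grid: tuple = PI_TABLE_BW_GRID
    min_stratum_n: int = DEFAULT_MIN_STRATUM_N
    fence_k: float = DEFAULT_FENCE_K
    deviance_cutoff_pct: float = 10.0
    r2_gate: float = allometry.DEFAULT_R2_GATE
    linearity_threshold: float = pspline.DEFAULT_LINEARITY_THRESHOLD
    level: float = 0.95
    out_dir: str | None = None
    make_plots: bool = False

    def validate(self) -> None:
        if not self.variables:
            raise ValueError("config field 'variables' must not be empty")
        unknown = [v for v in self.variables if v not in VARIABLES]
        if unknown:
            raise ValueError(f"config field 'variables' has unknown entries {unknown}")
        if not self.bw_grid or list(self.bw_grid) != sorted(self.bw_grid):
            raise ValueError("config field 'bw_grid' must be nonempty and ascending")
        for name in ("min_stratum_n", "fence_k", "deviance_cutoff_pct",
                     "r2_gate", "linearity_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name!r} must be positive")
        if self.input_path is None and not self.simulate:
            raise ValueError("either 'input_path' or 'simulate' is required")


@dataclass
class ReportBundle:
    config: PipelineConfig
    cohort: Cohort
    outlier_report: object
    fits_all: dict  # variable -> AllometricFit (all nonsighthound)
    fits_immaculate: dict
    constants: dict  # variable -> IndexConstants
    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: dict  # variable -> DataFrame
    table4: pd.DataFrame
    linearity: dict  # variable -> LinearityReport
    group_comparison: dict  # variable -> GroupComparison
    observer_table: pd.DataFrame
    fs_cutoff: object
    run_log: list = field(default_factory=list)


def _stage(run_log, name):
    run_log.append(name)
    log.info("pipeline stage: %s", name)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    config.validate()
    run_log: list[str] = []

    _stage(run_log, "load")
    try:
        if config.simulate:
            cohort = generate_cohort(SimConfig(seed=config.seed, truth=default_truth()))
        else:
            cohort = read_cohort(config.input_path, strict=False)
    except Exception as err:
        raise RuntimeError(f"pipeline stage 'load' failed: {err}") from err

    def stage(name, fn):
        _stage(run_log, name)
        try:
            return fn()
        except Exception as err:
            raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err

    screened, outrep = stage(
        "screen",
        lambda: screen_cohort(cohort, min_stratum_n=config.min_stratum_n,
                              k=config.fence_k),
    )

    group_all = screened.nonsighthound()
    group_imm = screened.immaculate()

    fits_all = stage(
        "fit",
        lambda: {
            v: allometry.fit_allometric(group_all, v, level=config.level)
            for v in config.variables
        },
    )
    fits_imm = stage(
        "fit-immaculate",
        lambda: {
            v: allometry.fit_allometric(group_imm, v, level=config.level)
            for v in config.variables
        },
    )

    linearity = stage(
        "validate-linearity",
        lambda: {
            v: pspline.linearity_check(fits_all[v], group_all,
                                       threshold=config.linearity_threshold)
            for v in config.variables
        },
    )

    comparison = stage(
        "compare-groups",
        lambda: {
            v: pspline.group_upper_limit_difference(
                group_all, group_imm, v, config.bw_grid
            )
            for v in config.variables
        },
    )

    constants = stage(
        "constants",
        lambda: {
            v: allometry.index_constants(fits_all[v], group_all)
            for v in config.variables
        },
    )

    table3 = stage(
        "pi-table",
        lambda: {
            v: allometry.pi_table(constants[v], config.bw_grid, level=config.level)
            for v in config.variables
        },
    )

    dev_rows = stage(
        "breed-deviance",
        lambda: breeds_mod.breed_deviance(
            screened.healthy(),
            {v: fits_all[v] for v in config.variables},
            cutoff_pct=config.deviance_cutoff_pct,
        ),
    )
    table4 = breeds_mod.deviance_table(dev_rows)

    observer_table = stage(
        "observer",
        lambda: observer_mod.rva_table(screened.healthy(), config.variables),
    )

    fs_cutoff = stage(
        "fs-cutoff",
        lambda: allometry.weight_independent_cutoff(
            group_all, "FS", r2_gate=config.r2_gate
        ),
    )

    table1 = pd.DataFrame(
        [
            {
                "variable": v,
                "a_all": round(fits_all[v].a, 2),
                "b_all": round(fits_all[v].b, 3),
                "r2_all": round(fits_all[v].r2, 3),
                "a_immaculate": round(fits_imm[v].a, 2),
                "b_immaculate": round(fits_imm[v].b, 3),
                "r2_immaculate": round(fits_imm[v].r2, 3),
            }
            for v in config.variables
        ]
    )
    table2 = pd.DataFrame(
        [
            {
                "variable": v,
                **{f"p{p:g}": round(c, 2) for p, c in sorted(
                    constants[v].constants.items(), reverse=True)},
                "exponent": round(constants[v].exponent, 3),
            }
            for v in config.variables
        ]
    )

    bundle = ReportBundle(
        config=config,
        cohort=screened,
        outlier_report=outrep,
        fits_all=fits_all,
        fits_immaculate=fits_imm,
        constants=constants,
        table1=table1,
        table2=table2,
        table3=table3,
        table4=table4,
        linearity=linearity,
        group_comparison=comparison,
        observer_table=observer_table,
        fs_cutoff=fs_cutoff,
        run_log=run_log,
    )
    if config.out_dir is not None:
        write_bundle(bundle, config.out_dir)
    return bundle


def write_bundle(bundle: ReportBundle, out_dir) -> Path:
    """Write every table of the bundle as CSV/JSON (and optional plots)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = dataclasses.asdict(bundle.config)
    cfg["run_log"] = bundle.run_log
    (out / "run_config.json").write_text(json.dumps(cfg, indent=2, default=str))
    write_cohort(bundle.cohort, out / "screened_cohort.csv")
    bundle.table1.to_csv(out / "table1_allometric_fits.csv", index=False)
    bundle.table2.to_csv(out / "table2_index_constants.csv", index=False)
    for v, t in bundle.table3.items():
        t.to_csv(out / f"table3_pi_{v}.csv", index=False)
    bundle.table4.to_csv(out / "table4_breed_deviance.csv", index=False)
    bundle.observer_table.to_csv(out / "observer_rva.csv", index=False)
    lin = {
        v: dataclasses.asdict(r) for v, r in bundle.linearity.items()
    }
    (out / "linearity_reports.json").write_text(json.dumps(lin, indent=2))
    comp = {
        v: {"mean_upper_diff_cm": c.mean_upper_diff, "group_effect_cm": c.group_effect}
        for v, c in bundle.group_comparison.items()
    }
    (out / "group_comparison.json").write_text(json.dumps(comp, indent=2))
    (out / "outlier_report.txt").write_text(bundle.outlier_report.summary() + "\n")
    fsc = bundle.fs_cutoff
    fs_payload = (
        dataclasses.asdict(fsc)
        if dataclasses.is_dataclass(fsc) and not isinstance(fsc, type)
        else {"note": str(fsc)}
    )
    (out / "fs_cutoff.json").write_text(json.dumps(fs_payload, indent=2))
    if bundle.config.make_plots:
        from .plots import scatter_pi_plot

        for v, fit in bundle.fits_all.items():
            scatter_pi_plot(
                bundle.cohort.nonsighthound(), fit, out / f"scatter_pi_{v}.png"
            )
    return out
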