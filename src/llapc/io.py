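"""Run configuration, pipeline orchestration, and preprocessing helpers.

The pipeline runs the full chain for each category in a study: filter the
incidence grid, estimate (or load) the period and cohort coefficients,
correct the rates, estimate the hazard curve, and compare each non-reference
category against the reference via the relative-hazard machinery. All
artifacts are written as full-precision CSV/JSON; display rounding happens
only in the human-readable report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .effects import (
    EffectEstimates,
    effects_to_frame,
    estimate_effects,
    load_supplied_coefficients,
    write_effects_json,
)
from .grid import AgeGrid, CohortLayout, PeriodGrid, apply_filters, read_grid_csv
from .hazard import HazardCurve, correct_rates, estimate_hazard, write_curve_csv
from .relhazard import (
    averaged_relative_hazard,
    flag_outliers,
    ratio_series,
    series_to_json,
    weighted_slope,
)

log = logging.getLogger("llapc")


@dataclass
class RunConfig:
    """Everything a pipeline run needs, mirroring the standard study setup.

    Defaults encode the lung-cancer configuration: 18 five-year age groups
    usable from ages 35-39, six periods from 1975, a strict >15-case filter,
    anchors at the last period and the eighth cohort, and a single-pass
    |z| > 2 outlier rule against the weighted mean.
    """

    input_csv: str | Path = ""
    reference: int = 0
    categories: tuple[int, ...] = ()
    n_age: int = 18
    m_periods: int = 6
    usable_from: int = 8
    first_period_start_year: int = 1975
    min_count: int = 15
    anchor_period: int | None = None
    anchor_cohort: int = 8
    outlier_mode: str = "mean"
    z_threshold: float = 2.0
    iterate_outliers: bool = False
    coefficients_json: str | Path | None = None
    se_floor: float | None = None
    out_dir: str | Path = "llapc_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "categories" in doc:
            doc["categories"] = tuple(doc["categories"])
        return cls(**doc)

    def grids_layout(self) -> tuple[AgeGrid, PeriodGrid, CohortLayout]:
        ages = AgeGrid.five_year(self.n_age, usable_from=self.usable_from)
        periods = PeriodGrid.five_year(self.first_period_start_year, self.m_periods)
        layout = CohortLayout.from_grids(
            ages, periods, first_period_start_year=self.first_period_start_year
        )
        return ages, periods, layout


def age_standardize(rates, weights, ses=None, counts=None) -> tuple[float, float]:
    """Direct age standardization of single-age rates within a group.

    ``rate = sum w_a r_a`` with weights normalized to 1 over the group's
    strata (the standard population's age distribution), and
    ``SE^2 = sum w_a^2 SE_a^2``. Stratum SEs may be supplied directly or
    derived as ``r_a / sqrt(n_a)`` from case counts.
    """
    rates = np.asarray(rates, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if rates.size == 0:
        raise ValueError("empty age group")
    if weights.shape != rates.shape:
        raise ValueError("weights must match rates")
    if np.any(weights < 0) or weights.sum() == 0:
        raise ValueError("weights must be non-negative with a positive sum")
    w = weights / weights.sum()
    if ses is None:
        if counts is None:
            raise ValueError("supply stratum SEs or case counts")
        counts = np.asarray(counts, dtype=float)
        if np.any(counts <= 0):
            raise ValueError("counts must be positive to derive SEs")
        ses = rates / np.sqrt(counts)
    ses = np.asarray(ses, dtype=float)
    rate = float(np.sum(w * rates))
    se = float(np.sqrt(np.sum(w**2 * ses**2)))
    return rate, se


def _effects_for(grid, config: RunConfig) -> EffectEstimates:
    if config.coefficients_json is not None:
        return load_supplied_coefficients(config.coefficients_json)
    return estimate_effects(
        grid,
        anchor_period=config.anchor_period,
        anchor_cohort=config.anchor_cohort,
    )


def hazard_from_grid(grid, config: RunConfig, label: str = "") -> tuple[HazardCurve, EffectEstimates]:
    """Filter, estimate coefficients, correct, and estimate the hazard."""
    filtered = apply_filters(grid, config.min_count, config.usable_from)
    if filtered.n_present == 0:
        raise ValueError("no usable cells after filtering")
    eff = _effects_for(filtered, config)
    corr = correct_rates(filtered, eff)
    curve = estimate_hazard(corr, se_floor=config.se_floor, label=label)
    return curve, eff


def compare_curves(curves: dict[int, HazardCurve], config: RunConfig) -> dict:
    """Relative-hazard comparison of every non-reference curve.

    Returns a JSON-serializable summary holding, per category: the ratio
    series, flagged outliers, the averaged relative hazard with SE, and the
    weighted slope diagnostics with and without exclusions.
    """
    ref = curves[config.reference]
    out: dict = {"reference": config.reference, "categories": {}}
    for c, curve in sorted(curves.items()):
        if c == config.reference:
            continue
        series = ratio_series(curve, ref)
        series = flag_outliers(
            series,
            mode=config.outlier_mode,
            z_threshold=config.z_threshold,
            iterate=config.iterate_outliers,
        )
        avg = averaged_relative_hazard(series)
        slope_excl, slope_excl_se = weighted_slope(series, use_flagged=False)
        out["categories"][str(c)] = {
            "series": {
                "age_midpoint": series.midpoints.tolist(),
                "ratio": series.r.tolist(),
                "se": series.se.tolist(),
                "outlier": series.outlier.tolist(),
            },
            "averaged_relative_hazard": avg.R,
            "averaged_relative_hazard_se": avg.se,
            "excluded_ages": list(avg.excluded),
            "slope_all_points": avg.slope,
            "slope_all_points_se": avg.slope_se,
            "slope_excluding_outliers": slope_excl,
            "slope_excluding_outliers_se": slope_excl_se,
            "_series_obj": series,
            "_avg_obj": avg,
        }
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Full run from a long-format CSV of incidence grids to a result bundle.

    Writes coefficients, hazard curves, relative-hazard series and a summary
    JSON under ``config.out_dir``; the directory is populated atomically
    (nothing is left behind on failure). Returns the summary dictionary.
    """
    ages, periods, layout = config.grids_layout()
    grids = read_grid_csv(config.input_csv, ages, periods, layout)
    if not grids:
        raise ValueError("no usable cells: input contains no grids")
    categories = config.categories or tuple(sorted(grids))
    if config.reference not in grids:
        raise ValueError(f"reference category {config.reference} not in input")
    curves: dict[int, HazardCurve] = {}
    effects: dict[int, EffectEstimates] = {}
    run_log: list[str] = [f"llapc {__version__}"]
    for c in categories:
        grid = grids[c]
        filtered = apply_filters(grid, config.min_count, config.usable_from)
        dropped = grid.n_present - filtered.n_present
        run_log.append(
            f"category {c}: {grid.n_present} cells, {dropped} dropped by "
            f"filters (min_count={config.min_count} strict, "
            f"usable_from={config.usable_from})"
        )
        if filtered.n_present == 0:
            raise ValueError(f"no usable cells for category {c} after filtering")
        eff = _effects_for(filtered, config)
        corr = correct_rates(filtered, eff)
        if corr.n_dropped_missing_coeff:
            run_log.append(
                f"category {c}: {corr.n_dropped_missing_coeff} cells dropped "
                "for missing coefficients"
            )
        curves[c] = estimate_hazard(corr, se_floor=config.se_floor, label=str(c))
        effects[c] = eff
    summary = compare_curves(curves, config)
    summary["config"] = {
        k: (str(v) if isinstance(v, Path) else v)
        for k, v in dataclasses.asdict(config).items()
    }
    summary["schema_version"] = 1
    summary["log"] = run_log
    for c, entry in summary["categories"].items():
        run_log.append(
            f"category {c} vs {config.reference}: R = "
            f"{entry['averaged_relative_hazard']:.4f} +/- "
            f"{entry['averaged_relative_hazard_se']:.4f}, outliers at ages "
            f"{entry['excluded_ages']} (mode={config.outlier_mode}, "
            f"|z|>{config.z_threshold})"
        )
    _write_bundle(summary, curves, effects, config)
    return summary


def _write_bundle(summary, curves, effects, config: RunConfig) -> None:
    out_dir = Path(config.out_dir)
    staging = Path(tempfile.mkdtemp(prefix="llapc_", dir=out_dir.parent or "."))
    try:
        for c, curve in curves.items():
            write_curve_csv(curve, staging / f"hazard_category{c}.csv")
        for c, eff in effects.items():
            write_effects_json(eff, staging / f"effects_category{c}.json")
            effects_to_frame(eff).to_csv(
                staging / f"effects_category{c}.csv", index=False,
                float_format="%.17g",
            )
        for c, entry in summary["categories"].items():
            series_to_json(
                entry["_series_obj"], entry["_avg_obj"],
                staging / f"relhazard_category{c}.json",
            )
        clean = {
            k: v for k, v in summary.items()
        }
        clean["categories"] = {
            c: {k: v for k, v in entry.items() if not k.startswith("_")}
            for c, entry in summary["categories"].items()
        }
        with open(staging / "summary.json", "w") as fh:
            json.dump(clean, fh, indent=1)
        if out_dir.exists():
            shutil.rmtree(out_dir)
        staging.rename(out_dir)
    except BaseException:
        shutil.rmtree(staging, ignore_errors=True)
        raise
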