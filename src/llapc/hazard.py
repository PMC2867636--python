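"""Rate correction and age-specific hazard estimation.

Once period and cohort coefficients are in hand, every observed rate is
corrected to ``I* = I / (v_j u_l)``, which under the multiplicative model
is an unbiased reading of the age-specific hazard ``h(t_i)``. The hazard
at each age is then the inverse-variance weighted mean of its corrected
cells across periods, with SE ``(sum of weights)^{-1/2}`` -- the
minimum-variance linear combination for independent normal estimates.

The correction divides by coefficients usually estimated from the same
grid; the induced correlation between cells is ignored, a first-order
approximation that holds when coefficients of variation are small.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .effects import EffectEstimates
from .grid import AgeGrid, IncidenceGrid


@dataclass
class CorrectedGrid:
    """Corrected rates ``I*_{i,j} = I_{i,j} / (v_j u_l)`` with propagated SEs.

    NaN marks absent cells; a cell is present exactly when the source cell
    and both of its coefficients are. ``n_dropped_missing_coeff`` counts
    source cells lost to an unestimated coefficient.
    """

    ages: AgeGrid
    value: np.ndarray
    se: np.ndarray
    category: int
    anchors: tuple[int, int]
    n_dropped_missing_coeff: int = 0

    @property
    def present_mask(self) -> np.ndarray:
        return ~np.isnan(self.value)


@dataclass
class HazardCurve:
    """Age-specific hazard estimates ``h*(t_i)`` per 100,000 person-years.

    Arrays run over the age grid; NaN marks ages with no contributing
    cells. ``n_cells`` is how many periods contributed to each age.
    ``anchors`` records the (period, cohort) anchor pair the coefficients
    were normalized to -- curves are comparable only under equal anchors.
    """

    midpoints: np.ndarray
    h: np.ndarray
    se: np.ndarray
    n_cells: np.ndarray
    category: int = 0
    label: str = ""
    anchors: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.midpoints = np.asarray(self.midpoints, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        self.n_cells = np.asarray(self.n_cells, dtype=int)
        if not (self.midpoints.shape == self.h.shape == self.se.shape == self.n_cells.shape):
            raise ValueError("curve arrays must share one shape")
        present = ~np.isnan(self.h)
        if np.any(self.h[present] <= 0) or np.any(self.se[present] <= 0):
            raise ValueError("present hazard values and SEs must be positive")

    @property
    def present_mask(self) -> np.ndarray:
        return ~np.isnan(self.h)

    def to_frame(self) -> pd.DataFrame:
        m = self.present_mask
        return pd.DataFrame(
            {
                "age_midpoint": self.midpoints[m],
                "hazard": self.h[m],
                "se": self.se[m],
                "n_cells": self.n_cells[m],
            }
        )


def correct_rates(grid: IncidenceGrid, eff: EffectEstimates) -> CorrectedGrid:
    """Correct observed rates for period and cohort effects.

    For each present cell, ``I* = I / (v_j u_l)`` with first-order SE

        SE^2[I*] = (1/(v u))^2 SE_I^2 + (I/(v^2 u))^2 SE_v^2
                   + (I/(v u^2))^2 SE_u^2.

    A non-positive coefficient raises ``ValueError``; an absent (NaN)
    coefficient drops the cell and increments the dropped-cell counter.
    """
    n, m = grid.ages.n_age, grid.periods.m_periods
    if eff.v.size != m:
        raise ValueError("period coefficient count does not match the grid")
    if eff.u.size != grid.layout.k_cohorts:
        raise ValueError("cohort coefficient count does not match the layout")
    value = np.full((n, m), np.nan)
    se = np.full((n, m), np.nan)
    dropped = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            I = grid.rate[i - 1, j - 1]
            if np.isnan(I):
                continue
            l = grid.cohort_of(i, j)
            v, sv = eff.v[j - 1], eff.v_se[j - 1]
            u, su = eff.u[l - 1], eff.u_se[l - 1]
            if np.isnan(v) or np.isnan(u):
                dropped += 1
                continue
            if v <= 0 or u <= 0:
                raise ValueError(
                    f"non-positive coefficient at cell (i={i}, j={j}): v={v}, u={u}"
                )
            sI = grid.se[i - 1, j - 1]
            value[i - 1, j - 1] = I / (v * u)
            se[i - 1, j - 1] = np.sqrt(
                (sI / (v * u)) ** 2
                + (I / (v**2 * u)) ** 2 * sv**2
                + (I / (v * u**2)) ** 2 * su**2
            )
    return CorrectedGrid(
        grid.ages, value, se, grid.category, eff.anchors, dropped
    )


def estimate_hazard(
    corr: CorrectedGrid, se_floor: float | None = None, label: str = ""
) -> HazardCurve:
    """Inverse-variance weighted hazard per age group.

    ``h*(t_i)`` is the weighted mean of the corrected cells across periods
    with weights ``w = 1/SE^2``; its SE is ``(sum w)^{-1/2}``. Ages with no
    present cells are absent from the curve. A present cell with SE = 0
    would take infinite weight and is rejected; ``se_floor`` (same units as
    the rates) substitutes a minimum SE instead when set.
    """
    n = corr.ages.n_age
    h = np.full(n, np.nan)
    se_out = np.full(n, np.nan)
    n_cells = np.zeros(n, dtype=int)
    for i in range(n):
        present = corr.present_mask[i]
        if not present.any():
            continue
        vals = corr.value[i, present]
        ses = corr.se[i, present].copy()
        if se_floor is not None:
            ses = np.maximum(ses, se_floor)
        if np.any(ses == 0):
            raise ValueError(
                f"corrected cell with SE=0 in age group {i + 1}; "
                "set se_floor to handle degenerate SEs explicitly"
            )
        w = 1.0 / ses**2
        h[i] = np.sum(w * vals) / np.sum(w)
        se_out[i] = 1.0 / np.sqrt(np.sum(w))
        n_cells[i] = int(present.sum())
    if not np.any(~np.isnan(h)):
        raise ValueError("no usable cells: hazard curve would be empty")
    return HazardCurve(
        corr.ages.midpoints, h, se_out, n_cells,
        category=corr.category, label=label, anchors=corr.anchors,
    )


def write_curve_csv(curve: HazardCurve, path) -> None:
    """CSV with age_index, age_midpoint, hazard, se, n_cells (full precision)."""
    m = curve.present_mask
    frame = pd.DataFrame(
        {
            "age_index": np.arange(1, curve.midpoints.size + 1)[m],
            "age_midpoint": curve.midpoints[m],
            "hazard": curve.h[m],
            "se": curve.se[m],
            "n_cells": curve.n_cells[m],
        }
    )
    frame.to_csv(path, index=False, float_format="%.17g")


def write_curve_json(curve: HazardCurve, path) -> None:
    m = curve.present_mask
    doc = {
        "category": curve.category,
        "label": curve.label,
        "anchors": list(curve.anchors) if curve.anchors else None,
        "age_midpoint": curve.midpoints[m].tolist(),
        "hazard": curve.h[m].tolist(),
        "se": curve.se[m].tolist(),
        "n_cells": curve.n_cells[m].tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
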