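"""Synthetic incidence grids with known ground truth, and packaged fixtures.

The generator draws rates from the multiplicative model
``I_{i,j,c} = v_j u_l (R_c h(t_i)) (1 + eps)`` with relative
(coefficient-of-variation) normal noise, matching the normality-of-rates
assumption that the >15-case filter justifies for real registry data.
Cell SEs are the oracle value ``cv x (noise-free product)`` so that
error-propagation checks have a clean target. Counts are set large so the
case-count filter passes everywhere.

Also ships, as packaged CSV fixtures, published age-specific hazard
estimates (with SEs) for first-primary lung cancer in white men and women
in three SEER 9 areas -- San Francisco-Oakland (category 0), Connecticut
(1) and Detroit (2), 1975-2004, anchored at period 2000-04 and the 1925-29
birth cohort -- so every relative-hazard stage is testable without any
registry download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .grid import AgeGrid, CohortLayout, IncidenceGrid, PeriodGrid
from .hazard import HazardCurve

FIXTURE_SEXES = ("men", "women")
FIXTURE_AREAS = {
    0: "san_francisco_oakland",
    1: "connecticut",
    2: "detroit",
}
FIXTURE_ANCHORS = (6, 8)  # period 2000-04, birth cohort 1925-29


@dataclass
class TruthSpec:
    """Ground truth for one synthetic study.

    ``v_true`` (per period), ``u_true`` (per cohort) and ``h_true`` (per
    age, category 0, cases per 100,000 person-years) are strictly positive;
    ``R_true`` maps each non-reference category to a constant hazard
    multiplier. ``cv`` is the relative noise level (0 = exact model).
    """

    ages: AgeGrid
    periods: PeriodGrid
    layout: CohortLayout
    v_true: np.ndarray
    u_true: np.ndarray
    h_true: np.ndarray
    R_true: dict[int, float] = field(default_factory=dict)
    cv: float = 0.02
    seed: int = 0
    count: int = 1000

    def __post_init__(self) -> None:
        self.v_true = np.asarray(self.v_true, dtype=float)
        self.u_true = np.asarray(self.u_true, dtype=float)
        self.h_true = np.asarray(self.h_true, dtype=float)
        if self.v_true.size != self.periods.m_periods:
            raise ValueError("v_true length must equal m_periods")
        if self.u_true.size != self.layout.k_cohorts:
            raise ValueError("u_true length must equal k_cohorts")
        if self.h_true.size != self.ages.n_age:
            raise ValueError("h_true length must equal n_age")
        for name in ("v_true", "u_true", "h_true"):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"{name} must be strictly positive")
        if any(R <= 0 for R in self.R_true.values()):
            raise ValueError("R_true multipliers must be strictly positive")
        if self.cv < 0:
            raise ValueError("cv must be non-negative")

    @classmethod
    def standard(
        cls,
        v_true=None,
        u_true=None,
        h_true=None,
        R_true: dict[int, float] | None = None,
        cv: float = 0.02,
        seed: int = 0,
    ) -> "TruthSpec":
        """The standard lung-cancer layout: 18 age groups, 6 periods, 16 cohorts.

        Default effects are mild geometric trends (period ratio 1.05, cohort
        ratio 1.02 per step) around a lognormal-shaped hazard peaking near
        age 75 at ~250 per 100,000 -- the scale and shape of the packaged
        lung-cancer curves.
        """
        ages = AgeGrid.five_year()
        periods = PeriodGrid.five_year()
        layout = CohortLayout.from_grids(ages, periods, first_period_start_year=1975)
        if v_true is None:
            v_true = 1.05 ** np.arange(periods.m_periods)
        if u_true is None:
            u_true = 1.02 ** np.arange(layout.k_cohorts)
        if h_true is None:
            t = ages.midpoints
            h_true = 250.0 * np.exp(-0.5 * ((np.log(t) - np.log(75.0)) / 0.35) ** 2)
        return cls(
            ages, periods, layout, v_true, u_true, h_true,
            R_true=dict(R_true or {}), cv=cv, seed=seed,
        )


def generate_grid(
    spec: TruthSpec, category: int = 0, rng: np.random.Generator | None = None
) -> IncidenceGrid:
    """Draw one noisy incidence grid for the given category.

    The noise term ``eps ~ Normal(0, cv^2)`` is truncated at -0.9 (redrawn)
    to keep rates positive. Cells whose cohort index falls outside the
    layout (ages below ``usable_from`` in late periods) are left absent.
    Reproducible: a fixed ``spec.seed`` (when ``rng`` is not given) yields
    bit-identical grids, with one independent substream per category.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(category + 1)[-1])
    R = spec.R_true.get(category, 1.0) if category != 0 else 1.0
    n, m = spec.ages.n_age, spec.periods.m_periods
    rate = np.full((n, m), np.nan)
    se = np.full((n, m), np.nan)
    count = np.full((n, m), np.nan)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            l = j - i + spec.layout.offset
            if not 1 <= l <= spec.layout.k_cohorts:
                continue
            clean = spec.v_true[j - 1] * spec.u_true[l - 1] * R * spec.h_true[i - 1]
            eps = rng.normal(0.0, spec.cv) if spec.cv > 0 else 0.0
            while eps <= -0.9:
                eps = rng.normal(0.0, spec.cv)
            rate[i - 1, j - 1] = clean * (1.0 + eps)
            se[i - 1, j - 1] = spec.cv * clean
            count[i - 1, j - 1] = spec.count
    return IncidenceGrid(
        spec.ages, spec.periods, spec.layout, rate, se, count, category=category
    )


def generate_study(
    spec: TruthSpec, categories: tuple[int, ...] = (0, 1)
) -> dict[int, IncidenceGrid]:
    """One grid per category, independent noise streams, shared truth."""
    return {c: generate_grid(spec, c) for c in categories}


def _fixture_frame(sex: str) -> pd.DataFrame:
    if sex not in FIXTURE_SEXES:
        raise ValueError(f"sex must be one of {FIXTURE_SEXES}, got {sex!r}")
    ref = resources.files("llapc.fixtures") / f"seer9_lung_hazard_{sex}.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def reference_hazard_curves(sex: str) -> dict[int, HazardCurve]:
    """Packaged lung-cancer hazard curves, one per SEER 9 area.

    Returns ``{0: San Francisco-Oakland, 1: Connecticut, 2: Detroit}`` for
    the given sex, ages 37.5-87.5 (11 groups), values per 100,000
    person-years, all anchored at (period 2000-04, cohort 1925-29).
    """
    frame = _fixture_frame(sex)
    out: dict[int, HazardCurve] = {}
    for code, sub in frame.groupby("category"):
        sub = sub.sort_values("age_index")
        out[int(code)] = HazardCurve(
            sub["age_midpoint"].to_numpy(),
            sub["hazard"].to_numpy(),
            sub["se"].to_numpy(),
            np.full(len(sub), 6, dtype=int),
            category=int(code),
            label=f"{sub['area'].iloc[0]} ({sex})",
            anchors=FIXTURE_ANCHORS,
        )
    return out
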