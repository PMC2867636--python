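"""Domain types for the age-period-cohort data cube.

Incidence rates are laid out on an age-group x calendar-period grid; birth
cohorts run along the Lexis diagonals (cohort = period - age), so a single
integer offset maps any in-range ``(i, j)`` cell to its cohort index ``l``.
All user-facing indices are 1-based, matching the conventional ``i, j, l``
notation of age-period-cohort analysis; internal arrays are 0-based.

Missing cells are first-class: a cell filtered out (or never observed) is
NaN in every array, and every downstream estimator skips it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

GRID_CSV_COLUMNS = [
    "category",
    "sex",
    "age_index",
    "age_midpoint",
    "period_index",
    "rate",
    "se",
    "count",
]


@dataclass(frozen=True)
class AgeGrid:
    """Layout of 5-year age groups.

    Parameters
    ----------
    n_age : int
        Number of age groups.
    midpoints : ndarray
        Age-interval midpoints ``t_i`` in years, strictly increasing.
    labels : tuple of str
        One label per group (e.g. ``"35-39"``).
    usable_from : int
        First usable 1-based age index; earlier groups carry too few cases
        for rate estimates and are excluded from analysis.
    """

    n_age: int
    midpoints: np.ndarray
    labels: tuple[str, ...]
    usable_from: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "midpoints", np.asarray(self.midpoints, dtype=float))
        if self.midpoints.shape != (self.n_age,):
            raise ValueError("midpoints length must equal n_age")
        if len(self.labels) != self.n_age:
            raise ValueError("labels length must equal n_age")
        if np.any(np.diff(self.midpoints) <= 0):
            raise ValueError("age midpoints must be strictly increasing")
        if not 1 <= self.usable_from <= self.n_age:
            raise ValueError("usable_from must lie in [1, n_age]")

    @classmethod
    def five_year(
        cls, n_age: int = 18, start: float = 0.0, usable_from: int = 8,
        open_last: bool = True,
    ) -> "AgeGrid":
        """Standard 5-year layout: 0-4, 5-9, ..., with an open last group.

        The default (18 groups, usable from group 8, ages 35-39) matches the
        SEER-style grouping used for lung-cancer incidence, where groups
        under age 35 have statistically insignificant case counts.
        """
        midpoints = start + 2.5 + 5.0 * np.arange(n_age)
        labels = []
        for k in range(n_age):
            lo = int(start + 5 * k)
            if open_last and k == n_age - 1:
                labels.append(f"{lo}+")
            else:
                labels.append(f"{lo}-{lo + 4}")
        return cls(n_age, midpoints, tuple(labels), usable_from)


@dataclass(frozen=True)
class PeriodGrid:
    """Layout of 5-year calendar periods (e.g. 1975-79 ... 2000-04)."""

    m_periods: int
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.m_periods < 2:
            raise ValueError("at least two periods are required")
        if len(self.labels) != self.m_periods:
            raise ValueError("labels length must equal m_periods")

    @classmethod
    def five_year(cls, start_year: int = 1975, m_periods: int = 6) -> "PeriodGrid":
        labels = tuple(
            f"{start_year + 5 * j}-{(start_year + 5 * j + 4) % 100:02d}"
            for j in range(m_periods)
        )
        return cls(m_periods, labels)


@dataclass(frozen=True)
class CohortLayout:
    """Diagonal cohort indexing: ``l = j - i + offset``.

    A 5-year age group crossed with a 5-year period spans about nine birth
    years; this layout adopts the single-diagonal convention, so every cell
    on one ``j - i`` diagonal shares one cohort index. With ``offset`` equal
    to the number of age groups, the oldest group in the earliest period is
    cohort 1.
    """

    k_cohorts: int
    offset: int
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.k_cohorts < 1:
            raise ValueError("k_cohorts must be positive")
        if self.labels and len(self.labels) != self.k_cohorts:
            raise ValueError("labels length must equal k_cohorts")

    @classmethod
    def from_grids(
        cls,
        ages: AgeGrid,
        periods: PeriodGrid,
        offset: int | None = None,
        first_period_start_year: int | None = None,
    ) -> "CohortLayout":
        """Layout spanning the usable cells of the given age/period grids.

        Cohort count is determined by the usable diagonals:
        ``k = m_periods - usable_from + n_age``. For the standard lung-cancer
        layout (18 age groups, 6 periods, usable from group 8) this yields
        16 cohorts.
        """
        if offset is None:
            offset = ages.n_age
        k = periods.m_periods - ages.usable_from + ages.n_age
        labels: tuple[str, ...] = ()
        if first_period_start_year is not None:
            # Birth years of cohort l: start = Y0 + 5*(l - offset), so the
            # oldest group in the earliest period (l = 1) is the earliest
            # cohort (1890-94 for the 1975-2004 lung-cancer layout).
            labels = tuple(
                "{0}-{1:02d}".format(
                    first_period_start_year + 5 * (l - offset),
                    (first_period_start_year + 5 * (l - offset) + 4) % 100,
                )
                for l in range(1, k + 1)
            )
        return cls(k, offset, labels)


def cohort_index(i: int, j: int, layout: CohortLayout, ages: AgeGrid | None = None,
                 periods: PeriodGrid | None = None) -> int:
    """Cohort index ``l = j - i + offset`` for 1-based age ``i``, period ``j``.

    Cells on the same ``j - i`` diagonal always share ``l``. Raises
    ``IndexError`` when ``i``/``j`` fall outside the supplied grids or the
    resulting ``l`` is outside ``[1, k_cohorts]``.
    """
    if ages is not None and not 1 <= i <= ages.n_age:
        raise IndexError(f"age index i={i} outside [1, {ages.n_age}]")
    if periods is not None and not 1 <= j <= periods.m_periods:
        raise IndexError(f"period index j={j} outside [1, {periods.m_periods}]")
    if i < 1 or j < 1:
        raise IndexError(f"indices must be 1-based positive, got (i={i}, j={j})")
    l = j - i + layout.offset
    if not 1 <= l <= layout.k_cohorts:
        raise IndexError(
            f"cell (i={i}, j={j}) maps to cohort l={l} outside "
            f"[1, {layout.k_cohorts}]"
        )
    return l


@dataclass
class IncidenceGrid:
    """Observed age-adjusted incidence rates ``I_{i,j,c}(t_i)`` for one category.

    Arrays are ``(n_age, m_periods)``; NaN marks an absent cell. ``rate`` and
    ``se`` are cases per 100,000 person-years; ``count`` is the raw case
    count (NaN when not supplied).
    """

    ages: AgeGrid
    periods: PeriodGrid
    layout: CohortLayout
    rate: np.ndarray
    se: np.ndarray
    count: np.ndarray
    category: int = 0
    sex: str = ""

    def __post_init__(self) -> None:
        shape = (self.ages.n_age, self.periods.m_periods)
        for name in ("rate", "se", "count"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")
            setattr(self, name, arr)
        present = self.present_mask
        if np.any(self.rate[present] <= 0):
            raise ValueError("present rates must be strictly positive")
        if np.any(self.se[present] < 0) or np.any(np.isnan(self.se[present])):
            raise ValueError("present cells must carry a non-negative SE")
        counts = self.count[present]
        counts = counts[~np.isnan(counts)]
        if counts.size and (np.any(counts < 0) or np.any(counts != np.round(counts))):
            raise ValueError("counts must be non-negative integers")

    @property
    def present_mask(self) -> np.ndarray:
        return ~np.isnan(self.rate)

    @property
    def n_present(self) -> int:
        return int(self.present_mask.sum())

    def cohort_of(self, i: int, j: int) -> int:
        """Cohort index of 1-based cell ``(i, j)``."""
        return cohort_index(i, j, self.layout, self.ages, self.periods)

    def copy(self) -> "IncidenceGrid":
        return replace(
            self, rate=self.rate.copy(), se=self.se.copy(), count=self.count.copy()
        )


def apply_filters(
    grid: IncidenceGrid,
    min_count: int = 15,
    usable_from: int | None = None,
) -> IncidenceGrid:
    """Blank out cells failing the case-count and usable-age filters.

    A cell is retained only when its case count is *strictly larger* than
    ``min_count`` and its age index is at least ``usable_from`` (defaulting
    to the grid's own ``usable_from``). The count filter is applied per cell.
    Cells without a count are dropped whenever ``min_count > 0``. Filtering
    is idempotent and may leave the grid empty; downstream estimators refuse
    empty grids.
    """
    if usable_from is None:
        usable_from = grid.ages.usable_from
    out = grid.copy()
    keep = out.present_mask.copy()
    if min_count > 0:
        with np.errstate(invalid="ignore"):
            keep &= out.count > min_count  # NaN count compares False -> dropped
    keep[: usable_from - 1, :] = False
    drop = ~keep
    out.rate[drop] = np.nan
    out.se[drop] = np.nan
    out.count[drop] = np.nan
    return out


def grid_to_frame(grid: IncidenceGrid) -> pd.DataFrame:
    """Long-format view of present cells (one row per cell)."""
    rows = []
    for i in range(1, grid.ages.n_age + 1):
        for j in range(1, grid.periods.m_periods + 1):
            r = grid.rate[i - 1, j - 1]
            if np.isnan(r):
                continue
            rows.append(
                {
                    "category": grid.category,
                    "sex": grid.sex,
                    "age_index": i,
                    "age_midpoint": grid.ages.midpoints[i - 1],
                    "period_index": j,
                    "rate": r,
                    "se": grid.se[i - 1, j - 1],
                    "count": grid.count[i - 1, j - 1],
                }
            )
    return pd.DataFrame(rows, columns=GRID_CSV_COLUMNS)


def write_grid_csv(grids: list[IncidenceGrid] | IncidenceGrid, path) -> None:
    """Write one or more grids to long-format CSV (full float precision)."""
    if isinstance(grids, IncidenceGrid):
        grids = [grids]
    frame = pd.concat([grid_to_frame(g) for g in grids], ignore_index=True)
    frame.to_csv(path, index=False, float_format="%.17g")


def read_grid_csv(
    path,
    ages: AgeGrid,
    periods: PeriodGrid,
    layout: CohortLayout | None = None,
) -> dict[int, IncidenceGrid]:
    """Read long-format CSV into one :class:`IncidenceGrid` per category.

    The layout of the grids (age midpoints, period count) must be supplied;
    the file carries only the cell values. Rows with duplicate
    ``(category, age_index, period_index)`` raise ``ValueError``.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = set(GRID_CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"grid CSV missing columns: {sorted(missing)}")
    if layout is None:
        layout = CohortLayout.from_grids(ages, periods)
    out: dict[int, IncidenceGrid] = {}
    for category, sub in frame.groupby("category"):
        if sub.duplicated(["age_index", "period_index"]).any():
            raise ValueError(f"duplicate cells for category {category}")
        shape = (ages.n_age, periods.m_periods)
        rate = np.full(shape, np.nan)
        se = np.full(shape, np.nan)
        count = np.full(shape, np.nan)
        ii = sub["age_index"].to_numpy(dtype=int) - 1
        jj = sub["period_index"].to_numpy(dtype=int) - 1
        if ii.min() < 0 or ii.max() >= ages.n_age or jj.min() < 0 or jj.max() >= periods.m_periods:
            raise ValueError("age/period index outside the declared layout")
        rate[ii, jj] = sub["rate"].to_numpy(dtype=float)
        se[ii, jj] = sub["se"].to_numpy(dtype=float)
        count[ii, jj] = sub["count"].to_numpy(dtype=float)
        sexes = sub["sex"].astype(str).unique()
        out[int(category)] = IncidenceGrid(
            ages, periods, layout, rate, se, count,
            category=int(category), sex=sexes[0] if len(sexes) == 1 else "",
        )
    return out
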