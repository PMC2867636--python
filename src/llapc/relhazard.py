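"""Relative hazards between exposure categories.

The ratio of two categories' age-specific hazards, r(t_i) = h_c(t_i)/h_0(t_i),
measures the relative hazard of category c against the reference at each
age. When the ratios fluctuate about a constant, that constant -- the
averaged relative hazard R -- is estimated by the inverse-variance weighted
mean over ages, after excluding high-influence outliers flagged by their
standardized residual against the weighted fit. A weighted least-squares
slope against age midpoint serves as the diagnostic for any residual age
trend.

Curves estimated under different anchor pairs are not comparable (the
anchoring rescales both period and cohort coefficients); ratio construction
therefore refuses mismatched anchors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .hazard import HazardCurve

Z95 = 1.96


@dataclass
class RelativeHazardSeries:
    """Per-age hazard ratios for one category pair ``(c, reference)``.

    ``ci_low``/``ci_high`` are the 95% bounds ``r -/+ 1.96 SE``; ``outlier``
    flags points excluded from averaging (all False until
    :func:`flag_outliers` runs).
    """

    midpoints: np.ndarray
    r: np.ndarray
    se: np.ndarray
    outlier: np.ndarray
    category: int
    reference: int
    anchors: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.midpoints = np.asarray(self.midpoints, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        self.outlier = np.asarray(self.outlier, dtype=bool)
        if not (self.midpoints.shape == self.r.shape == self.se.shape == self.outlier.shape):
            raise ValueError("series arrays must share one shape")
        if np.any(self.r <= 0) or np.any(self.se <= 0):
            raise ValueError("ratios and their SEs must be strictly positive")

    @property
    def ci_low(self) -> np.ndarray:
        return self.r - Z95 * self.se

    @property
    def ci_high(self) -> np.ndarray:
        return self.r + Z95 * self.se

    @property
    def n_points(self) -> int:
        return int(self.r.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age_midpoint": self.midpoints,
                "ratio": self.r,
                "se": self.se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "outlier": self.outlier,
            }
        )


@dataclass
class AveragedRelativeHazard:
    """Averaged relative hazard ``R`` with SE and the exclusions applied.

    ``R`` is the inverse-variance weighted mean of the unflagged ratios,
    ``se = (sum w)^{-1/2}``; ``excluded`` lists the age midpoints omitted as
    outliers; ``slope``/``slope_se`` are the all-points weighted-regression
    diagnostics when computed.
    """

    R: float
    se: float
    excluded: tuple[float, ...]
    weights: np.ndarray
    category: int
    reference: int
    slope: float | None = None
    slope_se: float | None = None


def ratio_series(
    numerator: HazardCurve, reference: HazardCurve
) -> RelativeHazardSeries:
    """Age-specific relative hazards with first-order SEs.

    ``r_i = h_c/h_0`` over the shared age support, with
    ``SE(r) = r sqrt((SE_c/h_c)^2 + (SE_0/h_0)^2)`` (independent numerator
    and denominator: the categories are distinct populations). Raises
    ``ValueError`` when the two curves were anchored differently.
    """
    if numerator.anchors is not None and reference.anchors is not None:
        if numerator.anchors != reference.anchors:
            raise ValueError(
                "hazard curves are comparable only under equal anchors: "
                f"{numerator.anchors} vs {reference.anchors}"
            )
    if numerator.midpoints.size != reference.midpoints.size or np.any(
        numerator.midpoints != reference.midpoints
    ):
        raise ValueError("curves must share one age grid")
    both = numerator.present_mask & reference.present_mask
    if not both.any():
        raise ValueError("curves share no ages with estimates")
    h1, s1 = numerator.h[both], numerator.se[both]
    h0, s0 = reference.h[both], reference.se[both]
    r = h1 / h0
    se = r * np.sqrt((s1 / h1) ** 2 + (s0 / h0) ** 2)
    return RelativeHazardSeries(
        numerator.midpoints[both], r, se, np.zeros(r.size, dtype=bool),
        category=numerator.category, reference=reference.category,
        anchors=numerator.anchors,
    )


def _weighted_mean(r: np.ndarray, se: np.ndarray) -> tuple[float, float]:
    w = 1.0 / se**2
    return float(np.sum(w * r) / np.sum(w)), float(1.0 / np.sqrt(np.sum(w)))


def _wls_line(t: np.ndarray, r: np.ndarray, se: np.ndarray):
    """Weighted LS fit r = a + b t; returns (a, b, se_a, se_b)."""
    if np.unique(t).size < 2:
        raise ValueError("degenerate design: need at least two distinct ages")
    w = 1.0 / se**2
    X = np.column_stack([np.ones_like(t), t])
    XtWX = X.T @ (w[:, None] * X)
    beta = np.linalg.solve(XtWX, X.T @ (w * r))
    cov = np.linalg.inv(XtWX)
    return beta[0], beta[1], np.sqrt(cov[0, 0]), np.sqrt(cov[1, 1])


def flag_outliers(
    series: RelativeHazardSeries,
    mode: str = "mean",
    z_threshold: float = 2.0,
    iterate: bool = False,
) -> RelativeHazardSeries:
    """Flag high-influence points by standardized residual.

    Fits the weighted constant (``mode="mean"``) or weighted line against
    age midpoint (``mode="trend"``) to the currently unflagged points, and
    flags every point with ``|r_i - fit_i| / SE(r_i) > z_threshold``.
    Single pass by default; ``iterate=True`` repeats until the flag set is
    stable. Raises ``ValueError`` if fewer than 3 points remain unflagged.
    """
    if series.n_points < 3:
        raise ValueError("outlier flagging needs at least 3 points")
    if mode not in ("mean", "trend"):
        raise ValueError(f"unknown mode {mode!r}")
    flags = series.outlier.copy()
    while True:
        keep = ~flags
        if keep.sum() < 3:
            raise ValueError("fewer than 3 points remain after outlier exclusion")
        if mode == "mean":
            fit, _ = _weighted_mean(series.r[keep], series.se[keep])
            fitted = np.full(series.n_points, fit)
        else:
            a, b, _, _ = _wls_line(
                series.midpoints[keep], series.r[keep], series.se[keep]
            )
            fitted = a + b * series.midpoints
        z = (series.r - fitted) / series.se
        new_flags = np.abs(z) > z_threshold
        if not iterate or np.array_equal(new_flags, flags):
            flags = new_flags
            break
        flags = new_flags
    if (~flags).sum() < 1:
        raise ValueError("all points flagged as outliers")
    return replace(series, outlier=flags)


def averaged_relative_hazard(
    series: RelativeHazardSeries, with_slope: bool = True
) -> AveragedRelativeHazard:
    """Inverse-variance weighted mean of the unflagged relative hazards.

    Flagged points are excluded from both the mean and its SE. The slope
    diagnostic, when requested and the series has >= 3 points, is the
    all-points weighted LS slope (reported regardless of flags).
    """
    keep = ~series.outlier
    if not keep.any():
        raise ValueError("no unflagged points to average")
    R, se = _weighted_mean(series.r[keep], series.se[keep])
    slope = slope_se = None
    if with_slope and series.n_points >= 3:
        slope, slope_se = weighted_slope(series, use_flagged=True)
    w = np.where(keep, 1.0 / series.se**2, 0.0)
    return AveragedRelativeHazard(
        R, se, tuple(series.midpoints[series.outlier].tolist()), w,
        series.category, series.reference, slope, slope_se,
    )


def weighted_slope(
    series: RelativeHazardSeries, use_flagged: bool = True
) -> tuple[float, float]:
    """Weighted LS slope of ratio against age midpoint, with its SE.

    ``use_flagged=True`` fits all points; ``False`` drops flagged outliers.
    """
    if series.n_points < 3:
        raise ValueError("slope fitting needs at least 3 points")
    keep = np.ones(series.n_points, dtype=bool) if use_flagged else ~series.outlier
    _, b, _, se_b = _wls_line(
        series.midpoints[keep], series.r[keep], series.se[keep]
    )
    return float(b), float(se_b)


def adjust_curve(curve: HazardCurve, avg: AveragedRelativeHazard | float) -> HazardCurve:
    """Divide a hazard curve by its averaged relative hazard.

    Scales both ``h`` and ``se`` by ``1/R`` to overlay the curve on the
    reference category's scale. The uncertainty of ``R`` itself is not
    propagated -- this is a display adjustment, not a new estimate.
    """
    R = avg.R if isinstance(avg, AveragedRelativeHazard) else float(avg)
    if R <= 0:
        raise ValueError("averaged relative hazard must be positive")
    return replace(curve, h=curve.h / R, se=curve.se / R)


def series_to_json(series: RelativeHazardSeries, avg: AveragedRelativeHazard, path) -> None:
    doc = {
        "category": series.category,
        "reference": series.reference,
        "age_midpoint": series.midpoints.tolist(),
        "ratio": series.r.tolist(),
        "se": series.se.tolist(),
        "ci_low": series.ci_low.tolist(),
        "ci_high": series.ci_high.tolist(),
        "outlier": series.outlier.tolist(),
        "averaged_relative_hazard": {
            "R": avg.R,
            "se": avg.se,
            "excluded_ages": list(avg.excluded),
            "slope": avg.slope,
            "slope_se": avg.slope_se,
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
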