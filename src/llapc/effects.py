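"""Estimation of period and cohort effect coefficients by ratio chaining.

The multiplicative model ``I_{i,j} = v_j u_l h(t_i)`` is identifiable only
up to anchoring (cohort = period - age), so one period coefficient and one
cohort coefficient are fixed to 1. Under the neighbor-cohort assumption --
adjacent 5-year birth cohorts have nearly equal effect coefficients -- the
same-age ratio of rates in adjacent periods,

    I_{i,j+1} / I_{i,j} = (v_{j+1}/v_j) (u_{l+1}/u_l)  ~  v_{j+1}/v_j,

estimates the adjacent-period effect ratio without any knowledge of the
hazard function h. Ratios are pooled over ages by inverse-variance
weighting, chained on the log scale, and anchored. Cohort ratios are then
estimated the same way from period-corrected rates ``I_{i,j}/v_j``.

This ratio-chaining estimator is this package's own construction of the
coefficient-estimation step; the neighbor-cohort assumption is its only
substantive input, and the documented bias of the period ratios is exactly
the neighbor-cohort drift ``u_{l+1}/u_l``. Externally estimated
coefficients can be supplied instead via :func:`load_supplied_coefficients`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import IncidenceGrid


@dataclass
class EffectEstimates:
    """Period coefficients ``v_j`` and cohort coefficients ``u_l`` with SEs.

    Anchored values are exactly 1 with SE exactly 0. NaN marks a coefficient
    that could not be estimated (e.g. a cohort disconnected from the anchor).
    ``provenance`` is ``"estimated"`` or ``"supplied"``.
    """

    v: np.ndarray
    v_se: np.ndarray
    u: np.ndarray
    u_se: np.ndarray
    anchor_period: int
    anchor_cohort: int
    provenance: str = "estimated"

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        self.v_se = np.asarray(self.v_se, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.u_se = np.asarray(self.u_se, dtype=float)
        if self.v.shape != self.v_se.shape or self.u.shape != self.u_se.shape:
            raise ValueError("value and SE arrays must have matching shapes")
        if not 1 <= self.anchor_period <= self.v.size:
            raise ValueError("anchor_period outside the period range")
        if not 1 <= self.anchor_cohort <= self.u.size:
            raise ValueError("anchor_cohort outside the cohort range")
        for arr, se, j0, kind in (
            (self.v, self.v_se, self.anchor_period, "period"),
            (self.u, self.u_se, self.anchor_cohort, "cohort"),
        ):
            present = ~np.isnan(arr)
            if np.any(arr[present] <= 0):
                raise ValueError(f"{kind} coefficients must be strictly positive")
            if np.any(se[present] < 0):
                raise ValueError(f"{kind} SEs must be non-negative")
            if not (arr[j0 - 1] == 1.0 and se[j0 - 1] == 0.0):
                raise ValueError(
                    f"{kind} anchor must be exactly 1 with SE 0, got "
                    f"{arr[j0 - 1]} +/- {se[j0 - 1]}"
                )

    @property
    def anchors(self) -> tuple[int, int]:
        return (self.anchor_period, self.anchor_cohort)


def _pool_ratios(num, num_se, den, den_se):
    """Inverse-variance pooled ratio of paired arrays.

    Each pair contributes ``a/b`` with first-order SE
    ``(a/b) sqrt((SE_a/a)^2 + (SE_b/b)^2)``; pairs with zero total SE get
    pooled exactly (infinite weight shortcut: if any SE is zero the pooled
    value is the plain weighted value with the zero-SE pairs dominating).
    Returns ``(value, se, n_pairs)``.
    """
    ratio = num / den
    with np.errstate(divide="ignore"):
        rel2 = (num_se / num) ** 2 + (den_se / den) ** 2
    se = ratio * np.sqrt(rel2)
    if np.any(se == 0):
        exact = ratio[se == 0]
        return float(exact.mean()), 0.0, int(ratio.size)
    w = 1.0 / se**2
    value = float(np.sum(w * ratio) / np.sum(w))
    return value, float(1.0 / np.sqrt(np.sum(w))), int(ratio.size)


def estimate_period_ratios(grid: IncidenceGrid) -> list[tuple[float, float]]:
    """Adjacent-period effect ratios ``v_{j+1}/v_j`` with SEs.

    For each adjacent period pair, pools the same-age rate ratios
    ``I_{i,j+1}/I_{i,j}`` over all ages where both cells are present, by
    inverse-variance weighting. Raises ``ValueError`` when a pair shares no
    present cells. The pooled ratio carries the neighbor-cohort drift
    ``u_{l+1}/u_l`` as a multiplicative bias.
    """
    m = grid.periods.m_periods
    out: list[tuple[float, float]] = []
    present = grid.present_mask
    for j in range(m - 1):
        shared = present[:, j] & present[:, j + 1]
        if not shared.any():
            raise ValueError(
                f"periods {j + 1} and {j + 2} share no present age groups"
            )
        value, se, _ = _pool_ratios(
            grid.rate[shared, j + 1], grid.se[shared, j + 1],
            grid.rate[shared, j], grid.se[shared, j],
        )
        out.append((value, se))
    return out


def chain_and_anchor(
    ratios: list[tuple[float, float]], anchor: int
) -> tuple[np.ndarray, np.ndarray]:
    """Turn adjacent ratios into anchored coefficients with propagated SEs.

    ``ratios[k]`` estimates ``x_{k+2}/x_{k+1}``; the chain is accumulated on
    the log scale and shifted so ``x_anchor = 1``. Squared relative errors
    add along the path from the anchor, so the anchor's SE is exactly 0.
    NaN ratios break the chain: coefficients beyond a break are NaN.
    """
    n = len(ratios) + 1
    if not 1 <= anchor <= n:
        raise ValueError(f"anchor {anchor} outside [1, {n}]")
    vals = np.array([r[0] for r in ratios], dtype=float)
    ses = np.array([r[1] for r in ratios], dtype=float)
    if np.any(vals[~np.isnan(vals)] <= 0):
        raise ValueError("ratios must be strictly positive")
    log_x = np.concatenate([[0.0], np.cumsum(np.log(vals))])
    relvar_cum = np.concatenate([[0.0], np.cumsum((ses / vals) ** 2)])
    x = np.exp(log_x - log_x[anchor - 1])
    # Relative variance of x_k is the sum of squared relative ratio errors
    # strictly between k and the anchor.
    relvar = np.abs(relvar_cum - relvar_cum[anchor - 1])
    se = x * np.sqrt(relvar)
    se[anchor - 1] = 0.0
    return x, se


def estimate_cohort_ratios(
    grid: IncidenceGrid, v: np.ndarray, v_se: np.ndarray | None = None
) -> list[tuple[float, float]]:
    """Adjacent-cohort effect ratios ``u_{l+1}/u_l`` after removing ``v``.

    A same-age pair of cells in adjacent periods sits on adjacent cohort
    diagonals, so ``(I_{i,j+1}/v_{j+1}) / (I_{i,j}/v_j) = u_{l+1}/u_l``
    (the hazard cancels). All such pairs with cohort pair ``(l, l+1)`` are
    pooled by inverse variance. Pairs touching a NaN period coefficient are
    skipped; a cohort pair with no usable cells yields ``(nan, nan)``.
    """
    if v_se is None:
        v_se = np.zeros_like(np.asarray(v, dtype=float))
    v = np.asarray(v, dtype=float)
    v_se = np.asarray(v_se, dtype=float)
    if v.size != grid.periods.m_periods:
        raise ValueError("v length must equal the number of periods")
    k = grid.layout.k_cohorts
    present = grid.present_mask
    buckets: dict[int, list[tuple[float, float, float, float]]] = {
        l: [] for l in range(1, k)
    }
    for i in range(1, grid.ages.n_age + 1):
        for j in range(1, grid.periods.m_periods):
            if not (present[i - 1, j - 1] and present[i - 1, j]):
                continue
            if np.isnan(v[j - 1]) or np.isnan(v[j]):
                continue
            l = grid.cohort_of(i, j)  # pair is (l, l+1)
            if l + 1 > k:
                continue
            a = grid.rate[i - 1, j] / v[j]
            b = grid.rate[i - 1, j - 1] / v[j - 1]
            a_rel2 = (grid.se[i - 1, j] / grid.rate[i - 1, j]) ** 2 + (
                v_se[j] / v[j]
            ) ** 2
            b_rel2 = (grid.se[i - 1, j - 1] / grid.rate[i - 1, j - 1]) ** 2 + (
                v_se[j - 1] / v[j - 1]
            ) ** 2
            buckets[l].append((a, a * np.sqrt(a_rel2), b, b * np.sqrt(b_rel2)))
    out: list[tuple[float, float]] = []
    for l in range(1, k):
        pairs = buckets[l]
        if not pairs:
            out.append((np.nan, np.nan))
            continue
        arr = np.array(pairs, dtype=float)
        value, se, _ = _pool_ratios(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3])
        out.append((value, se))
    return out


def estimate_cohort_effects(
    grid: IncidenceGrid,
    v: np.ndarray,
    anchor_cohort: int,
    v_se: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Anchored cohort coefficients ``u_l`` with SEs.

    Chains the pooled adjacent-cohort ratios from :func:`estimate_cohort_ratios`
    on the log scale and anchors at ``anchor_cohort``. Cohorts not connected
    to the anchor through present cells come back NaN (absent, never
    guessed). Raises ``ValueError`` if the anchor itself is unreachable.
    """
    ratios = estimate_cohort_ratios(grid, v, v_se)
    k = len(ratios) + 1
    if not 1 <= anchor_cohort <= k:
        raise ValueError(f"anchor cohort {anchor_cohort} outside [1, {k}]")
    vals = np.array([r[0] for r in ratios], dtype=float)
    ses = np.array([r[1] for r in ratios], dtype=float)
    u = np.full(k, np.nan)
    u_se = np.full(k, np.nan)
    u[anchor_cohort - 1] = 1.0
    u_se[anchor_cohort - 1] = 0.0
    # Walk outward from the anchor on the log scale; a missing adjacent
    # ratio disconnects everything beyond it on that side.
    log_u, relvar = 0.0, 0.0
    for l in range(anchor_cohort + 1, k + 1):  # forward: ratio (l-1) -> l
        r, s = vals[l - 2], ses[l - 2]
        if np.isnan(r):
            break
        log_u += np.log(r)
        relvar += (s / r) ** 2
        u[l - 1] = np.exp(log_u)
        u_se[l - 1] = u[l - 1] * np.sqrt(relvar)
    log_u, relvar = 0.0, 0.0
    for l in range(anchor_cohort - 1, 0, -1):  # backward: ratio l -> l+1
        r, s = vals[l - 1], ses[l - 1]
        if np.isnan(r):
            break
        log_u -= np.log(r)
        relvar += (s / r) ** 2
        u[l - 1] = np.exp(log_u)
        u_se[l - 1] = u[l - 1] * np.sqrt(relvar)
    return u, u_se


def estimate_effects(
    grid: IncidenceGrid,
    anchor_period: int | None = None,
    anchor_cohort: int = 8,
) -> EffectEstimates:
    """Full coefficient estimation: period ratios, chain, then cohorts.

    Defaults anchor the last period (the most recent diagnostic regime) and
    cohort 8 (the 1925-29 birth cohort in the standard lung-cancer layout).
    """
    if anchor_period is None:
        anchor_period = grid.periods.m_periods
    ratios = estimate_period_ratios(grid)
    v, v_se = chain_and_anchor(ratios, anchor_period)
    u, u_se = estimate_cohort_effects(grid, v, anchor_cohort, v_se)
    return EffectEstimates(
        v, v_se, u, u_se, anchor_period, anchor_cohort, provenance="estimated"
    )


def load_supplied_coefficients(source) -> EffectEstimates:
    """Validate externally estimated coefficients.

    ``source`` is a mapping (or path to a JSON document) with keys ``v``,
    ``v_se``, ``u``, ``u_se``, ``anchor_period``, ``anchor_cohort``.
    Non-positive values, missing anchors, or dimension mismatches raise
    ``ValueError``.
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "read"):
        if hasattr(source, "read"):
            source = json.load(source)
        else:
            with open(source) as fh:
                source = json.load(fh)
    try:
        eff = EffectEstimates(
            np.asarray(source["v"], dtype=float),
            np.asarray(source["v_se"], dtype=float),
            np.asarray(source["u"], dtype=float),
            np.asarray(source["u_se"], dtype=float),
            int(source["anchor_period"]),
            int(source["anchor_cohort"]),
            provenance="supplied",
        )
    except KeyError as exc:
        raise ValueError(f"supplied coefficients missing field {exc}") from exc
    return eff


def effects_to_frame(eff: EffectEstimates) -> pd.DataFrame:
    """Tabular view: kind in {period, cohort}, index, value, se, is_anchor."""
    rows = []
    for kind, vals, ses, anchor in (
        ("period", eff.v, eff.v_se, eff.anchor_period),
        ("cohort", eff.u, eff.u_se, eff.anchor_cohort),
    ):
        for idx in range(1, vals.size + 1):
            rows.append(
                {
                    "kind": kind,
                    "index": idx,
                    "value": vals[idx - 1],
                    "se": ses[idx - 1],
                    "is_anchor": idx == anchor,
                }
            )
    return pd.DataFrame(rows)


def write_effects_json(eff: EffectEstimates, path) -> None:
    doc = {
        "v": eff.v.tolist(),
        "v_se": eff.v_se.tolist(),
        "u": eff.u.tolist(),
        "u_se": eff.u_se.tolist(),
        "anchor_period": eff.anchor_period,
        "anchor_cohort": eff.anchor_cohort,
        "provenance": eff.provenance,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
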