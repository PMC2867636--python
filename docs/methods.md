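# Methods

## Model

Observed age-adjusted incidence rates on a 5-year age × 5-year period grid
are taken to factorize multiplicatively,

    I_{i,j,c}(t_i) = v_{j,c} · u_{l,c} · h_c(t_i),

with *t_i* the age-interval midpoint, *l = j − i + offset* the birth-cohort
index along the Lexis diagonal, and *c* the exposure category. A 5-year ×
5-year cell spans roughly nine birth years; the single-diagonal convention
assigns each cell the one cohort index of its diagonal, which for the
standard layout (18 age groups, 6 periods 1975–2004, ages 35+ usable)
yields exactly 16 cohorts, 1890–94 through 1965–69.

Rates are assumed normally distributed with known standard errors. This is
justified by the case-count filter: only cells with **more than 15 cases**
(strict inequality) enter any computation, so the normal approximation to
the rate's sampling distribution is adequate and Poisson machinery is not
needed. The filter is applied per cell; a per-age-group variant would also
be defensible, so the threshold and scope are configuration knobs
(`min_count`, applied strictly; `usable_from` for the age cutoff).

Age, period and cohort are linearly dependent, so (v, u) are identifiable
only up to two anchors: one period coefficient and one cohort coefficient
are fixed at 1 (default: the last period, and cohort 8 — 1925–29 in the
standard layout). All anchored quantities, and in particular hazard curves
from different categories, are comparable **only under equal anchors**;
`ratio_series` enforces this.

## Coefficient estimation by ratio chaining

The package estimates (v, u) without any assumption on the shape of h,
using only the *neighbor-cohort assumption*: adjacent 5-year cohorts have
nearly equal effect coefficients. For a fixed age row, the ratio of rates
in adjacent periods is

    I_{i,j+1} / I_{i,j} = (v_{j+1}/v_j) · (u_{l+1}/u_l) ≈ v_{j+1}/v_j,

independent of h. The estimator:

1. For each adjacent period pair, form the per-age ratios with first-order
   SEs, SE(a/b) = (a/b)·√((SE_a/a)² + (SE_b/b)²), and pool them by
   inverse-variance weights 1/SE² (pool-then-chain order; cells lacking an
   SE are excluded from pooling).
2. Chain the pooled ratios on the log scale (numerically symmetric in the
   ratio direction) and anchor: squared relative errors add along the path
   from the anchor, whose SE is exactly 0.
3. Remove v from the grid (I/v_j) and repeat the same construction on
   same-age adjacent-period pairs, which now estimate adjacent-cohort
   ratios u_{l+1}/u_l exactly (h cancels); pool per cohort pair, chain,
   anchor. A cohort unreachable from the anchor through present cells is
   reported absent (NaN), never guessed.

Pooling order, weighting and SE formulas here are this package's own
design; alternative orderings (chain-then-pool) would differ at second
order. **Known bias:** the adjacent-period ratio estimates v_{j+1}/v_j only
up to the neighbor-cohort drift u_{l+1}/u_l. With u geometric of per-cohort
ratio ρ, every period ratio is biased by exactly ρ (the simulator exposes
this scenario and a test pins the direction). When coefficients from other
software are preferred, `load_supplied_coefficients` validates and uses
them unchanged (`provenance="supplied"`).

## Hazard estimation

Corrected rates I* = I/(v·u) carry the first-order SE

    SE²[I*] = (SE_I/(vu))² + (I·SE_v/(v²u))² + (I·SE_u/(vu²))²,

and, the model being I* = h(t_i) + error, the minimum-variance estimate per
age group is the inverse-variance weighted mean across periods with
SE[h*] = (Σ w)^(−1/2). Two approximations are inherited deliberately from
the procedure the package implements: the corrected cells are treated as
independent although the coefficients were estimated from the same grid,
and coefficient/rate errors are propagated only to first order. Both are
accurate when coefficients of variation are small (a few percent). A
consequence measured by the test-bed: with coefficients estimated from the
same grid the propagated SE of downstream summaries understates the
replicate-to-replicate spread (shared coefficient errors move the whole
curve coherently); with externally supplied coefficients the propagated
SEs are calibrated, and the coverage tests condition on that case.

Degenerate inputs: a present cell with SE = 0 would take infinite weight
and is rejected; `se_floor` substitutes a minimum SE when the caller wants
such cells (e.g. noise-free synthetic grids) handled explicitly.

## Relative hazards

For categories c and 0 sharing anchors, r(t_i) = h_c/h_0 with
SE(r) = r·√((SE_c/h_c)² + (SE_0/h_0)²) — numerator and denominator are
independent (distinct populations); the within-category correlation through
shared anchors is ignored as above. 95% CIs are r ± 1.96·SE.

The averaged relative hazard R is the inverse-variance weighted mean of
the unflagged r_i with SE (Σ w)^(−1/2). Outliers are flagged by
standardized residual |r_i − fit_i|/SE(r_i) > 2 against the weighted
constant fit (mode `mean`, the default) or the weighted line against age
(mode `trend`); one pass by default, optionally iterated to a fixpoint.
The threshold 2 ≈ the 95% normal point; on the packaged tables it flags
the same high-influence points a regression analyst would remove by eye
(e.g. the age-42.5 point, r ≈ 1.77, in the women Connecticut series). One
borderline case is worth recording: in the women Detroit series the
age-47.5 point sits at z = 2.007 on the 2-decimal published inputs and is
therefore flagged alongside 42.5 and 87.5; with exclusions {42.5, 87.5}
only, the recomputed mean would be 1.318 rather than 1.310 — a difference
an order of magnitude below the series SE, attributable to rounding of the
published inputs.

The slope diagnostic is the weighted least-squares line r = a + b·t
(weights 1/SE²), with SE(b) from the weighted normal equations; it is
reported both for all points and excluding flagged points, the headline
value being the all-points fit. Display rounding (ratios to 2 decimals,
slopes to 4) happens only in the human-readable report; machine-readable
outputs keep full precision. Curve adjustment for shape comparison divides
h and SE by R without propagating SE[R] — a display transformation.

A note on published SE columns for per-age ratios: propagating the curve
SEs gives values ≈ half the SEs printed alongside the published ratio
tables (which appear to be 95% half-widths, ≈1.96× the SE), while the
published SEs of the averaged hazards match propagation. This package uses
propagated SEs throughout.

## Synthetic data

`TruthSpec`/`generate_grid` draw rates as v_j·u_l·(R_c·h(t_i))·(1 + ε),
ε ~ Normal(0, cv²) truncated at −0.9 (redrawn) for positivity — matching
the normality-of-rates assumption rather than Poisson counts (a
Poisson-count mode is a labeled extension point, not implemented). Cell SEs
are the oracle value cv × noise-free rate, so propagation tests have an
exact target; counts are set to 1000 so the default filter retains every
cell. Defaults: the standard 18 × 6 layout; mild geometric period/cohort
trends (ratios 1.05 and 1.02 per step); a lognormal-shaped hazard peaking
near age 75 at ≈250 per 100,000, the scale and shape of the packaged
lung-cancer curves; cv = 2%, the level at which the published procedure's
approximations are comfortably valid (the tests also exercise 3–5%).
Categories receive independent noise substreams spawned from one seed;
runs are bit-reproducible.

What the generator does **not** emulate: Poisson sampling at small counts,
age-standardization error structure within 5-year groups, registry
artifacts (coding changes, late registration), or period–cohort
interactions. Passing tests therefore validate the estimators under the
model's own assumptions, not robustness to their violation.

Test problem sizes: coverage and calibration properties use 150–500
replicates of the standard 18 × 6 grid, enough to put the Monte-Carlo
error of a 95% coverage estimate near ±1%, and the whole suite runs in a
few seconds.

## Known limitations

- The neighbor-cohort bias (above) is inherent to the separation strategy;
  it cancels in between-category ratios when both categories share the
  same drift, which is exactly the use case the relative-hazard machinery
  targets.
- Propagated SEs ignore within-category correlations induced by shared
  coefficient estimates; comparisons across categories are unaffected at
  first order, but absolute curve SEs are optimistic when coefficients are
  estimated rather than supplied.
- No Poisson-likelihood fitting with a parametric hazard, no smoothing of
  coefficients, no heterogeneity test across ages, no multiple-testing
  control; the per-age estimates are deliberately nonparametric.
- Direct age standardization (`age_standardize`) requires user-supplied
  standard-population weights; no standard weight table ships with the
  package.
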