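# llapc

Age-specific hazard estimation and relative-hazard comparison in the
log-linear age-period-cohort (LLAPC) model.

Cancer registries report age-specific incidence rates that mix three
confounded time scales: age at diagnosis, calendar period (diagnostic
practice, registration changes) and birth cohort (generational exposures
such as smoking prevalence). Under the LLAPC model the observed rate in age
group *i*, period *j* factorizes as

```
I_{i,j,c}(t_i) = v_{j,c} · u_{l,c} · h_c(t_i),      l = j − i + offset
```

where *v_j* are period effect coefficients, *u_l* are cohort effect
coefficients along the Lexis diagonals, *h(t_i)* is the age-specific hazard
(the quantity of epidemiological interest, per 100,000 person-years) and
*c* indexes exposure categories of a categorical risk factor — in the
shipped application, three SEER 9 geographical areas. Because age, period
and cohort are linearly dependent, the coefficients are identifiable only
up to anchors (one *v* and one *u* fixed to 1); curves are comparable only
under equal anchors.

`llapc` implements the full computing procedure for populations with
different exposures:

1. **Coefficient estimation** (`llapc.effects`) — adjacent-period rate
   ratios pooled over ages by inverse-variance weighting, chained on the
   log scale and anchored, under the *neighbor-cohort assumption* (adjacent
   5-year cohorts have nearly equal coefficients); then adjacent-cohort
   ratios from period-corrected rates the same way. Externally estimated
   coefficients can be supplied instead.
2. **Rate correction and hazard estimation** (`llapc.hazard`) —
   `I* = I/(v_j u_l)` with first-order error propagation, then per age
   group the inverse-variance weighted mean across periods:
   `h*(t_i) = Σ_j w_{ij} I*_{ij} / Σ_j w_{ij}`, `SE[h*] = (Σ_j w_{ij})^{−1/2}`,
   with `w = 1/SE²`.
3. **Relative hazards** (`llapc.relhazard`) — per-age ratios
   `r(t_i) = h_c(t_i)/h_0(t_i)` with propagated SEs and 95% CIs, a
   standardized-residual outlier pass (|z| > 2 against the weighted fit),
   the averaged relative hazard `R = Σ w_i r_i / Σ w_i` with
   `SE[R] = (Σ w_i)^{−1/2}`, weighted-least-squares slope diagnostics, and
   curve adjustment (division by R) for shape comparison.
4. **Synthetic studies** (`llapc.simulate`) — grids drawn from the
   multiplicative model with known truth and relative normal noise, plus
   packaged hazard-curve estimates for first-primary lung cancer in white
   men and women in San Francisco-Oakland, Connecticut and Detroit
   (SEER 9, 1975–2004) so every stage runs without any registry download.

## Worked example

The packaged lung-cancer curves through the relative-hazard stage:

```sh
$ llapc report --fixtures men
SEER 9 lung cancer, white men, 1975-2004 (reference: San Francisco-Oakland)
  category 1: R = 1.31 +/- 0.02, slope (all points) 0.0023
  category 2: R = 1.53 +/- 0.02, outliers at ages [77.5], slope (all points) -0.0027
```

Category 1 is Connecticut, category 2 Detroit. The averaged relative hazard
says lung-cancer hazard in white men is about 1.31× the San
Francisco-Oakland level in Connecticut and 1.53× in Detroit, roughly
uniformly across ages 37.5–87.5: the weighted regression slopes of the
ratio series against age are near zero (0.0023 per year for Connecticut),
so a single multiplier summarizes the geographic contrast. For Detroit one
high-leverage point (age 77.5) is excluded by the |z| > 2 rule before the
mean is recomputed. The same library calls are available programmatically:

```python
from llapc import ratio_series, flag_outliers, averaged_relative_hazard
from llapc.simulate import reference_hazard_curves

curves = reference_hazard_curves("men")
series = flag_outliers(ratio_series(curves[1], curves[0]))
avg = averaged_relative_hazard(series)
print(f"{avg.R:.2f} +/- {avg.se:.2f}")   # 1.31 +/- 0.02
```

A full run from incidence grids (here synthetic, truth R = 1.4):

```sh
llapc simulate truth.yaml --out grids.csv --seed 3
llapc relhazard grids.csv --out-dir run/
```

which writes coefficient tables, hazard curves, the ratio series and a
`summary.json` result bundle under `run/`.

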