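# Methods

`airlag` implements a quasi-Poisson distributed-lag time-series analysis of
daily air-pollutant exposure and hospital-admission counts, together with a
synthetic-data generator that makes the whole pipeline testable against a
known truth. This note documents the model, the generator, the numerical
choices, and what the validation studies do and do not demonstrate.

## The regression model

Daily admission counts `Y_t` are modelled with a log link and a
quasi-Poisson variance assumption `Var(Y_t) = φ·μ_t`:

```
log E[Y_t] = β₀ + Σᵢ CB(xᵢ,t; L, lag basis)
           + ns(AT_t, 3) + ns(RH_t, 3) + ns(t, 7·years) + DOW_t
```

* `CB(x; L, ·)` is the distributed-lag cross-basis: the tensor product of an
  exposure-dimension basis and a lag-dimension basis over lags `0..L`
  (default `L = 7`, the acute-effect window standard in this literature).
  Column `(j, k)` at day `t` is `Σ_l B_var_j(x_{t−l})·B_lag_k(l)`, var-major
  ordering.
* `ns(·, df)` is a natural cubic spline with fixed df: 3 each for daily mean
  temperature and relative humidity, and 7 df per year over the sequential
  day index for long-term trend and seasonality. The time spline is over the
  day index spanning the whole study, not day-of-year: a `7 × years` df
  basis on a 1–366 variable would be ill-posed, while on the day index it is
  the standard "7 df/year" seasonal-control convention.
* `DOW` is six day-of-week dummies, Monday reference. Only contrasts enter
  any reported quantity, so the reference choice is immaterial.

Because every df is fixed a priori, the additive model is an ordinary GLM on
a constructed design matrix. Fitting is IRLS (via statsmodels' Poisson
family); point estimates equal Poisson ML, and the coefficient covariance is
scaled by the Pearson dispersion `φ̂ = X²/(n − p)` (deviance-based available
behind a flag). Rows whose lagged exposures are undefined (the first `L`
days) are dropped from the fit and the count is logged; the design is
rank-checked and aliased columns are reported by name.

### Spline construction

Natural cubic splines are built from a cubic B-spline basis with the two
second-derivative boundary constraints applied through a QR projection (the
`splines::ns` construction). Interior knots sit at equally spaced quantiles
of the data, boundary knots at the data range; without the constant spanned,
a `df`-column basis carries `df − 1` interior knots. Evaluation beyond the
boundary knots extrapolates linearly using the boundary value and first
derivative, which is what makes exposure-response prediction grids safe near
the data edge. Duplicate quantile knots (heavily tied data) are collapsed
with a warning and the effective df reduced, rather than failing.

### Lag bases

Two lag-dimension bases are first-class:

* **ns, 4 df, spanning the constant** on the integer lags 0..7 — the
  conventional smooth lag curve and the reporting default;
* **indicator (one column per lag)** — the unconstrained lag model.

The validation studies use the indicator basis. Their simulated truth is an
effect concentrated at a single lag, which is outside the span of a smooth
4-df lag spline; with the smooth basis those studies would measure basis
misspecification (a real phenomenon, but not the estimator property under
test). With the indicator basis the model is correctly specified and bias
and CI coverage are interpretable as estimator calibration.

### Reported quantities

Per-increment relative risks (10 μg/m³; 1 mg/m³ for CO, which is measured
in mg/m³) require the linear exposure basis, under which centering cancels
from every contrast. Single-day log-RR at lag `l` is
`increment·Σ_k θ_k B_lag_k(l)`; cumulative 0..k effects sum the lag
dimension with full covariance propagation; standard errors are delta-method
quadratic forms in the dispersion-scaled covariance. 95% intervals use
z = 1.96 (the Wald convention of the reported literature; the exact normal
quantile is a parameter). Exposure-response curves use a 3-df natural-spline
exposure basis centered at the minimum observed concentration, with
extrapolated grid points flagged.

## Attributable burden

For a threshold `T` (PM2.5 presets: WHO 25, Chinese Grade I 35, Grade II 75
μg/m³, 24-h targets) and a per-unit log-RR `β`, each exceedance day
contributes the attributable number

```
AN_t = n_t · (RR_t − 1)/RR_t,   RR_t = exp(β·(C_t − T)),
```

summed by calendar year; non-exceedance days contribute zero and a day
exactly at the target is not an exceedance (strict `>`). This is the
standard attributable-number form; it is isolated in one function so an
alternative (e.g. `n_t·(RR_t − 1)` on a baseline) can be swapped. `β`
defaults to the main-model single-day lag-0 linear effect per unit,
configurable. Yearly totals are returned unrounded together with a rounded
display value.

## Annual stratified models and the trend test

Year-by-year effects refit the full single-pollutant model on each calendar
year (time spline 7 df within the year, same meteorology/DOW terms). The
cross-basis window reaches back into the preceding December so lags at the
start of a year are defined; only the first year loses its leading `L` days.
The per-1-unit RR at a stated single-day lag (default lag 4) is extracted
per year, and a precision-weighted least-squares trend test (log-RR on year,
weights 1/se²) plus the year/log-RR Spearman correlation summarise the
interannual pattern.

## Sensitivity analyses

* **Time-spline df sweep**: the main model refit at 3–11 df/year with the
  pollutant held at its stated lag; deterministic given the data.
* **Two-pollutant models**: both pollutants enter one model as their
  concentrations at their respective optimal single-day lags. Pairs with
  |Spearman ρ| ≥ 0.6 are refused outright (with the computed ρ in the
  message) rather than silently fit, because jointly modelling strongly
  collinear exposures yields unstable coefficients.

## The synthetic-data generator

The generator emulates a heavily polluted northern-Chinese city panel and
is the ground-truth source for every validation study.

* **Pollutant marginals are lognormal**, moment-matched to the configured
  mean/SD. Observed concentration distributions of this kind are strongly
  right-skewed (city means near 58 μg/m³ PM2.5 with SDs near 48 and maxima
  above 400), which an additive Gaussian model cannot reproduce without
  heavy truncation bias.
* **Seasonality and trend act on the log scale**: a cosine with
  configurable amplitude and peak day (winter for combustion pollutants,
  summer for ozone) and a linear log-trend per year. The innovation
  variance is the total log-variance implied by the target mean/SD minus
  the seasonal (`a²/2`) and trend (`(span)²/12`) shares, and the log-mean is
  corrected by `ln I₀(a)` and the trend ramp factor, so the overall marginal
  still matches the configured moments.
* **Dependence**: innovations are a Gaussian copula with target Spearman
  correlations converted via `ρ = 2·sin(πρ_s/6)`, then passed through a
  stationary unit-variance AR(1) per pollutant. Non-positive-semi-definite
  targets are rejected with the offending matrix. The ozone–temperature
  rank correlation emerges from their shared summer seasonality rather
  than the copula.
* **Counts** follow the analysis model's mean structure (baseline log rate
  ~log 20, seasonal cosine with winter peak, mild weekend dip) and are
  negative binomial with `Var = φμ` (exactly Poisson at φ = 1) — the
  quasi-Poisson assumption specifies only moments, and NB2 with matched
  moments is the natural sampling law. Optional per-year multipliers on
  the exposure contribution emulate an attenuating association for the
  trend-recovery study. Sex/age strata are binomial splits (75% male,
  78% aged ≥65).
* **Warm-up**: `max_lag` extra leading days are simulated before the
  nominal start date so every analyzable day has a full lag history; the
  exposure-only series includes them, the counted panel starts at the
  configured start date.

The `shijiazhuang_like` preset fixes the marginals to published 2017–2024
descriptives for Shijiazhuang, log-trends to the published first-to-last
year declines, rank correlations of 0.5–0.85 among the combustion
pollutants with ozone negatively related, dispersion φ = 1.3, and a true
lag-0 PM2.5 effect of RR 1.01 per 10 μg/m³.

**What the generator does not emulate**: spatial (multi-station) structure,
chemical-transport dynamics, measurement error in exposure assignment,
count autocorrelation beyond what the seasonal/exposure structure induces,
epidemic-period shocks, and long-term demographic drift. Passing tests
therefore show that the estimators are correct and calibrated when the
model is correctly specified under realistic marginals, dependence and
overdispersion — not that the model is correct for any particular real
city.

## Validation studies and problem sizes

All studies derive replicate seeds from a `SeedSequence`, so they are
deterministic given the base seed.

* **Parameter recovery** — 200 replicates of the 8-year preset (2,922 days;
  2,915 fitted after lag exclusion), true lag-0 RR 1.01 per 10 μg/m³,
  φ = 1.3, seasonal confounding on: mean recovered RR and 95% CI coverage.
* **Trend recovery** — 100 seeds each for a per-unit lag-4 effect decaying
  linearly to zero over 8 years (share of seeds with year/log-RR Spearman
  ρ < −0.5) and for a constant effect (share with a non-significant
  weighted trend test).
* **df-sweep robustness** — 50 seeds; at each, nine refits at 3–11 df/year;
  share of seeds where all nine CIs cover the truth.
* **Two-pollutant confounding** — 100 seeds of a two-pollutant world
  (SO2/O3 analogue, rank correlation 0.5, effect only on O3): mean
  attenuation of the proxy's log-RR upon adjustment.

These sizes put the whole suite around a minute and a half of compute while
leaving Monte-Carlo error well below every decision margin.

## Numerical conventions and degenerate inputs

* IRLS convergence: relative deviance change below 1e−9 (statsmodels
  default iterations capped at 50); non-convergence and |η| > 30
  (separation-like divergence) raise rather than return garbage.
* Descriptive quantiles use linear interpolation (the value at position
  `q·(n−1)` of the sorted array); P25 of 1..100 is 25.75 under this
  convention.
* Cold season is November–March (northern-China heating season); the
  contrast is reported descriptively only.
* Spearman matrices use average ranks for ties; constant variables yield
  NaN entries and are listed in the result's `attrs["undefined"]`.
* Exceedance ties: a concentration exactly at a threshold is not an
  exceedance.
* `percent_change` returns the raw value plus 1-decimal display and
  integer headline roundings, since published texts mix both.

## Known limitations

* Meteorology is adjusted with fixed 3-df splines, not lag-distributed
  temperature terms; heat- or cold-wave lag structure is out of scope.
* The quasi-Poisson variance model cannot represent autocorrelated
  residual overdispersion; no HAC/robust errors are provided.
* Annual models estimate within-year effects with 7 df of within-year
  seasonal control, which is generous for 365 observations; very weak
  effects will often be non-significant year by year even when the pooled
  model detects them — the same behaviour reported in the literature this
  pipeline mirrors.
* The attribution formula conditions on the fitted β as fixed; its CI is
  not propagated into yearly excess-case totals.
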