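# Methods

## Problem and model

The analysis treats per-capita cigarette sales `y` of a province-year as
a draw from a conditional distribution given the province's real price
per pack and real per-capita GDP.  A demand model is fitted to every
*other* province's records (leave-one-province-out, LOPO) and the
conditional `t/100` and `(100−t)/100` quantiles evaluated at the held-out
province's covariates form a symmetric prediction interval.  With
correctly specified quantiles the interval contains the observation with
probability `(1 − t/100) − t/100` — 0.8 at the default `t = 10`.  Sales
outside the interval are anomalous; the gap is quantified relative to
the violated bound (UAR above, LAR below), which makes the measure a
dimensionless share of the bound and comparable across provinces and
years.

Because the held-out province is unseen, the models condition only on
price and GDP — no province identity or fixed effect reaches the
estimator.  Cross-province heterogeneity that price and GDP do not
explain therefore widens the intervals; this is intentional (an interval
is the range of sales *reasonable for any province* with those
covariates) but it bounds how small an anomaly can be resolved (see
Limitations).

## Quantile estimators

**Linear quantile regression.**  Coefficients minimize the mean check
loss; the solver is iteratively reweighted least squares
(`statsmodels.QuantReg`, `max_iter = 2000`).  Correctness is defined by
the objective, not the algorithm: the tests compare the attained pinball
objective with brute-force grid minima.  The design matrix is checked for
rank deficiency via near-zero QR pivots and the offending columns are
named in the error.

**Quantile regression forest.**  Tree structure comes from a standard
random-forest regressor (bootstrap resampling, `n_trees = 500`,
`min_leaf = 5`, all features considered per split — there are only two).
Prediction keeps every training response: for a query `x`, each tree
contributes weight `1/|leaf(x)|` to the training points sharing its leaf,
weights are averaged over trees (over all `n` training points), and the
conditional quantile is read off the weighted empirical CDF with the
**type-1 (left-continuous inverse)** convention — the smallest response
whose cumulative weight reaches α.  The convention is stated because a
mid-point or interpolating convention changes small-leaf predictions.

**Non-crossing.**  Per query row, predictions are sorted across quantile
levels.  A consequence used by the tests: one fitted model evaluated at
nested symmetric levels yields nested intervals, so the `t = 5` anomaly
set is a subset of the `t = 10` set.

**Response scale.**  The pipeline fits sales in levels by default (the
anomaly ratios are defined on level sales); `log_log = True` switches to
a constant-elasticity form (log response on log features) and
exponentiates the predicted bounds, which preserves coverage because the
transform is monotone.  The default model family is the linear one; the
forest is selected per run via the `model:` config block.

## Anomaly quantification

`UAR = (y − p_u)/p_u` for observations above the upper bound,
`LAR = (y − p_l)/p_l` (negative) below the lower bound; boundary
equality counts as normal.  National per-year averages are taken over the
anomalous provinces only — a year with none contributes 0, not a gap — 
with a config switch (`denominator: all`) to divide by all provinces
instead for sensitivity.  Summaries report |LAR| so both series are
positive shares.  The group decomposition assigns each upper-anomalous
record's UAR to its province's group and divides by the total count of
upper-anomalous records, so the components sum to the national average
exactly (machine precision), every year.

## Synthetic generator

The generator emulates the Spanish provincial panel's scale and
structure without reproducing its (undeposited) values:

- **Demand**: `log y = β₀ + u_p + β_price·log price + β_gdp·log gdp + ε`
  with defaults `β₀ = 4.0`, `β_price = −0.5` (price elasticity),
  `β_gdp = +0.4` (income elasticity), province effects
  `u_p ~ N(0, 0.25²)` and noise `ε ~ N(0, 0.08²)`.  The elasticities are
  conventional demand-study magnitudes, not estimates from any dataset.
- **Price**: a common per-year mean path ramping 1.25 → 4.95 real
  euros/pack (mean ≈ 3.1, temporal SD ≈ 1.2) with province jitter
  SD 0.05 — price variation is mostly temporal, as in the real panel
  where province price means are nearly identical.
- **GDP**: province-level means uniform on [17, 36] thousand real euros
  with 1 %/year growth and small lognormal jitter.
- **Calibration guard**: province effects are truncated so each
  province's structural mean sales — anomaly multiplier included — stays
  in [65, 290] packs/adult/year, keeping every province mean inside the
  emulated span [60, 300] that encloses the observed Spanish province
  means (73.08–267.40).  The truncation binds only in the tails and
  preserves the exact log-linear structure (checked by an exact linear
  solve when `σ_noise = 0`).
- **Anomalies** are multiplicative on sales from a start year onward,
  matching the ratio form of UAR/LAR: the default injection is three
  excess provinces ×1.6 (two labelled cross-border, one tourism) and
  three deficit provinces ×0.7, active over the whole period.  Ground
  truth (multiplier, label, group) is emitted per cell.

What the generator does **not** emulate: serial dependence of the noise,
price endogeneity, smoking-prevalence trends distinct from the price
path, substitute products, and anomalies that grow over time.  Passing
recovery tests therefore show that the pipeline finds multiplicative
level shifts against smooth demand — not that it would resolve every
real-world distortion.

## Determinism and numerics

All randomness flows from a single seed: replicate studies draw child
seeds from a seed sequence, and each province's forest fit uses a child
seed derived from the master seed and the province name (CRC32), so
results are invariant to province iteration order; interval construction
also canonicalizes panel row order.  Predicted intervals are checked
finite; non-finite bounds abort with the province named.  The weighted
quantile search uses an absolute tolerance of 1e−12 when comparing
cumulative weights to α so exact-fraction CDF steps (e.g. 0.1 at the
10th of 100 equal weights) resolve to the intended order statistic.

## Study sizes

The packaged Monte-Carlo studies run at the emulated study scale — 47
provinces × 16 years (752 observations per panel) over 20 replicate
seeds — for both the coverage study (well-specified generator: no
province effects, no anomalies, log-log linear quantile model) and the
recovery study (default generator and pipeline).  The coverage check
compares the pooled empirical coverage with the analytic 0.8 within
three Monte-Carlo standard errors of a proportion,
`3·sqrt(0.8·0.2/15040) ≈ 0.01`; the pooled-proportion SE is used because
per-panel coverage concentrates far below the binomial scale (check-loss
fits balance their training sample), while any *fitted* quantile model
carries a finite-sample undercoverage of order p/n that is part of the
quantity being measured, not Monte-Carlo noise.

## Known limitations

- With the default generator dispersion, price and GDP leave a
  cross-province log-scale spread of ≈ 0.26 unexplained, so the 80 %
  interval spans roughly ×[0.71, 1.40] around the conditional centre.
  Injected effects of ×1.6 / ×0.7 sit close to those bounds: detection
  of such anomalies is partial (a province with an unlucky random effect
  hides inside the band), and the detected ratio magnitude is measured
  relative to the violated bound, hence substantially smaller than
  `multiplier − 1`.  Larger multipliers, smaller province heterogeneity,
  or covariates that explain more of the cross-province spread all
  sharpen recovery.
- The LOPO design pools all years of the training provinces into one fit;
  it does not track structural change within the period beyond what the
  price path carries.
- Ratios quantify the gap to the *bound*, not to the unobservable
  counterfactual "true" sales; they are lower bounds on the distortion
  in that sense.
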