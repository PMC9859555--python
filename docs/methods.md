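# Methods

## The forecasting problem

Monthly soil-moisture records at several depths (10–200 cm, kg/m³) are to
be extrapolated one to two years ahead from co-located meteorological and
vegetation series: precipitation P (mm/month), soil evaporation SE
(mm/month), NDVI, leaf area index LAI (m²/m²) and the vegetation coverage
rate VCR (fraction). The package implements two routes and the protocol for
comparing them.

## Route A: water balance with a depth coefficient

For a flat semi-arid steppe the monthly soil-water budget is dominated by
vertical exchange: runoff in and out roughly cancel, and groundwater
exchange is taken as balanced. What remains is

    Δβ_t = s·P_t − SE_t − IC_t ,

the monthly increment of surface soil moisture, where IC is the canopy
interception flow and `s` (`precip_scale`) rescales precipitation before it
enters the budget. The default is s = 1/30, the calibration under which the
package's bundled reference table is internally consistent; s = 1 recovers
the plain budget. The increments carry mm-derived magnitudes but are added
directly to the kg/m³ moisture state without a density conversion — a
deliberate faithful-reproduction choice, documented rather than "fixed",
since the depth coefficient below absorbs any constant unit factor.

Interception saturates with rainfall:

    IC_t = cp_t · ICmax · (1 − exp(−k·P_t / ICmax)),
    ICmax = 0.935 + 0.498·LAI − 0.00575·LAI²  (mm),

with cover fraction cp, density correction k (default 1) and maximum
storage ICmax from LAI. By default ICmax is computed once from the maximum
LAI of the window under study (`icmax_mode="window-max"`); a per-month mode
exists but the window-constant form is what reproduces the bundled
reference table. The ICmax quadratic is increasing over the entire
physically relevant LAI range (vertex near 43.3 m²/m²).

Moisture at depth h follows the linear recursion

    β_{h,t} = α·β_{h,t−1} + γ_h·Δβ_t ,

with adjustment coefficient α (default 1) and depth coefficient γ_h
translating the surface increment into a change at depth. The increment of
month t drives the change *into* month t; generation, fitting and
forecasting all use this same alignment. γ_h is estimated by OLS of the
observed one-month change on Δβ_t through the origin, reported with its
t-test p-value; `estimate_alpha=True` switches to a joint two-regressor fit
of (α, γ_h). Forecast moisture is floored at 0 (physical nonnegativity; the
recursion itself is unbounded below).

VCR is typically observed for only a short recent window, so missing months
are filled from NDVI by polynomial regression (degrees 1–3, OLS). Selection
maximises adjusted R² among candidates whose slope coefficients are all
significant at the 5% level; the intercept is exempt (the shipped reference
calibration's intercept is itself not significant). The fixed cubic
calibration for the reference steppe site,
VCR = 0.008 − 0.894·NDVI + 5.827·NDVI² − 5.778·NDVI³, ships as
`steppe_vcr_model()`; predictions are clipped to [0, 1] (clipping can be
disabled when comparing against raw regression output).

The full pipeline (`model_a_pipeline`) chains: VCR fill → seasonal-ARIMA
extrapolation of P, SE, LAI and VCR over the horizon (point forecasts
clipped to their physical ranges) → interception and Δβ forecast → per-depth
(α, γ) fits on history → recursive forecast from the last observation.
Stage failures are re-raised tagged with the stage name.

## Route B: direct seasonal ARIMA

Each depth's record is fit with a seasonal ARIMA(p,d,q)(P,D,Q)₁₂ selected
automatically: d by repeated KPSS testing at the 5% level (max 2), D by an
STL seasonal-strength heuristic (threshold 0.64, max 1), and (p,q,P,Q) by a
stepwise neighbourhood search minimising AIC — seeded at (2,2)×(1,1) with
single- and paired-coordinate moves, defaults p,q ≤ 5 and P,Q ≤ 2 — with
ties broken by BIC and then total order. An exhaustive grid mode exists for
verification; on small grids the stepwise result attains the exhaustive AIC
minimum in the test suite. Estimation is state-space maximum likelihood
(statsmodels SARIMAX); non-converging candidates are retried with a second
optimiser and otherwise skipped and logged, never fatal. A constant series
returns a flagged degenerate white-noise fit (σ² = 0) whose forecast is the
constant. A constant term is included only for d + D = 0.

Forecasts are innovations-based point predictions with Gaussian intervals.
Residual whiteness is assessed with the Ljung–Box statistic
Q = n(n+2)·Σ ρ̂_k²/(n−k) on χ²(lags − fitted_df), lags defaulting to 12 and
fitted_df to the number of estimated ARMA coefficients. Autocorrelations
are computed without demeaning (model residuals are taken as mean-zero);
the Monte-Carlo size at n = 200 sits within [0.03, 0.07] of the nominal 5%.

Published coefficient sets can be applied to a user's own history without
re-estimation (`apply_published_model`): the fixed polynomials run through
the Kalman filter with the innovation variance concentrated out, so point
forecasts are coefficient-exact and intervals are scaled from the filtered
residuals. Three reference baselines ship for 10/40/100 cm; the printed
200 cm form in the source material is internally inconsistent and is
deliberately not shipped.

## Evaluation protocol

MSE, RMSE, MAE and MAPE (percent) over a held-out window; the default split
trains through 2020-12 and tests from 2021-01. MAPE is reported absent with
a warning when any actual value is zero, rather than silently dropping
points. `compare_models` tabulates metric × depth × model and flags every
per-cell minimum (ties within 1e-9 relative are all flagged).

## Synthetic sites

The generator draws monthly records with the structure the method assumes:

* P: gamma draws (shape 1.5) around a monthly climatology allocating 74.4%
  of a 340 mm annual total to June–September; months with small
  climatological means are exactly zero half the time (mean preserved by
  doubling the wet draw), reproducing dry-season zero-rain months.
* SE: July-peaked cosine between about 0.6 and 27 mm/month with
  multiplicative lognormal noise; LAI: August-peaked cosine in
  [0.64, 0.98] m²/m² with small additive noise; NDVI = 0.62·LAI − 0.20
  (monotone affine); VCR from the fixed cubic calibration, with only the
  trailing 21 months exposed as "observed".
* Soil moisture per depth from the package's own recursion with
  configurable (γ_h, α, noise sd), defaults γ = (−0.1069, −0.1357, −0.0652,
  −0.0018) at (10, 40, 100, 200) cm, noise sd decreasing with depth
  (0.8, 0.6, 0.5, 0.05) to mimic the observed near-constancy at 200 cm,
  initial values near the observed depth means. Because truth follows the
  model's own dynamics, noise-free parameter recovery is exact and noisy
  recovery is an honest calibration check (|γ̂ − γ| < 3·SE at ≈ the nominal
  99.7% rate over 200 seeds at n = 120).
* A per-depth `process="seasonal"` mode substitutes a seasonal AR(1) cycle
  — a layer a direct time-series model should win — and `disturbance_ar1`
  adds serially correlated noise for misspecification probes.

What the generator does *not* emulate: spatial heterogeneity, snow and
frozen-soil processes, inter-depth coupling (each layer is driven
independently by the surface increment), and trend/regime changes in the
climate drivers. Passing tests therefore demonstrate correctness of the
estimation and forecasting machinery under the model's own assumptions, not
skill on real profiles.

## Numerical choices and problem sizes

Tolerances when reproducing the bundled 4-decimal reference columns are
1.5e-4: the printed inputs are themselves rounded to 4 decimals, which
propagates ~1.2e-4 into the outputs. Degenerate inputs are handled
explicitly: constant Δβ or rank-deficient designs raise singular-fit
errors; series shorter than 2·12 + 4 months restrict the ARIMA search to
nonseasonal models; a constant series short-circuits to a degenerate fit.
The test suite runs stepwise searches with reduced limits (p,q ≤ 2,
P,Q ≤ 1) and 9–10-year synthetic sites, which exercises every code path at
a fraction of the default search cost; Monte-Carlo checks use 200 seeds
(γ recovery) and 1000 seeds (Ljung–Box size).

## Known limitations

* The 1/30 precipitation scale is a calibration constant whose physical
  meaning is not established; it is exposed as configuration rather than
  hidden.
* Δβ is added to kg/m³ states without unit conversion (absorbed by γ).
* The recursion has no mean-reversion when α = 1, so multi-year forecasts
  inherit any drift in the mean increment.
* Interval forecasts are produced only by the ARIMA route; the
  water-balance route propagates point forecasts of the drivers without
  uncertainty.
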