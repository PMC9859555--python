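# soilwater

Depth-resolved soil-moisture forecasting for monthly site records, built
for semi-arid grassland profiles where moisture is observed at several
depths (e.g. 10/40/100/200 cm, kg/m³) alongside precipitation, soil
evaporation, NDVI and leaf area index.

Two forecasting routes share a common monthly time-series core:

* **Water-balance route (Model A).** The monthly surface increment is the
  simplified budget Δβ_t = s·P_t − SE_t − IC_t (runoff and groundwater
  exchange assumed to cancel on flat steppe terrain), with canopy
  interception IC_t = cp_t·ICmax·(1 − e^{−k·P_t/ICmax}) and
  ICmax = 0.935 + 0.498·LAI − 0.00575·LAI². Moisture at depth *h* then
  follows β_{h,t} = α·β_{h,t−1} + γ_h·Δβ_t, where the depth coefficient
  γ_h is estimated from history by regression of observed one-month
  changes on Δβ. Drivers are extrapolated over the forecast horizon with
  seasonal ARIMA; sparse cover-fraction records are filled from NDVI by
  polynomial regression.
* **Seasonal-ARIMA baseline (Model B).** Each depth's record is fit
  directly with an automatically selected ARIMA(p,d,q)(P,D,Q)₁₂ (KPSS for
  d, seasonal-strength for D, stepwise AIC search for the rest) and
  forecast with Gaussian intervals and Ljung–Box residual diagnostics.

An evaluation module scores both routes (MSE/RMSE/MAE/MAPE) on a held-out
window, and a synthetic-site generator draws realistic semi-arid monthly
records — summer-concentrated precipitation, seasonal evaporation and LAI
cycles, and moisture produced by the recursion itself with known
parameters — so the whole pipeline is testable end to end.

## Worked example

```python
import numpy as np
from soilwater import (InterceptionParams, intercept_max, interception_flow,
                       delta_beta, WaterBalanceConfig)
from soilwater.synthetic import SiteScenario, generate
from soilwater.water_balance import fit_depth_model

ic_max = intercept_max(0.983)            # max storage at the window's LAI peak
print(f"ICmax at LAI 0.983: {ic_max:.3f} mm")
params = InterceptionParams(ic_max=ic_max, k=1.0)
ic = interception_flow(0.2814, 83.1367, params)
print(f"July interception (cp 0.2814, P 83.1367): {ic:.4f} mm")
db = delta_beta(83.1367, 26.9849, ic, WaterBalanceConfig())
print(f"balance increment: {db:.4f}")

drivers, profile, truth = generate(SiteScenario(years=10, seed=1))
for depth in profile.depths:
    m = fit_depth_model(profile.series[depth], truth["dbeta"], depth_cm=depth)
    g = truth["depth_params"][depth].gamma
    print(f"{depth:>4} cm: gamma_hat {m.gamma:+.4f} (true {g:+.4f}, p {m.gamma_p:.2e})")
```

prints

```
ICmax at LAI 0.983: 1.419 mm
July interception (cp 0.2814, P 83.1367): 0.3993 mm
balance increment: -24.6130
  10 cm: gamma_hat -0.1003 (true -0.1069, p 2.38e-39)
  40 cm: gamma_hat -0.1334 (true -0.1357, p 3.46e-72)
 100 cm: gamma_hat -0.0666 (true -0.0652, p 1.82e-45)
 200 cm: gamma_hat -0.0017 (true -0.0018, p 9.05e-08)
```

The first three lines reproduce the bundled reference site's worked
numbers: the maximum canopy storage at the forecast window's LAI peak, a
saturated July interception flow, and the (negative, evaporation-dominated)
July balance increment at the default precipitation scale 1/30. The last
four lines show the depth coefficients recovered from ten years of noisy
synthetic data — each estimate lands close to its generating value, with
the deep 200 cm layer nearly decoupled from the surface (γ ≈ −0.002) and
the significance p-values tiny throughout.

The same workflows are available from a shell:

```sh
soilwater simulate --out site --years 10 --seed 1
soilwater forecast-a --input site/site.csv --out runA --horizon 21
soilwater forecast-b --input site/site.csv --out runB --horizon 21
soilwater compare --actuals site/site.csv --split 2021-01 \
    --forecast-a runA/forecast_a.csv --forecast-b runB/forecast_b.csv
```

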