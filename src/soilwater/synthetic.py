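"""Synthetic monthly site records for a temperate semi-arid steppe.

The generator emulates the statistical structure the forecasting method
assumes: precipitation concentrated in June–September (about 74% of an
annual total near 340 mm, with exactly-zero dry-season months),
phase-locked seasonal cycles in soil evaporation and leaf area index, NDVI
as a monotone function of LAI, cover fraction from the fixed NDVI
calibration, and soil moisture at each depth produced by the package's own
recursion β_t = α·β_{t−1} + γ_h·Δβ_t with known parameters plus Gaussian
noise.  Because the moisture dynamics are the model's own, parameter
recovery is a well-posed end-to-end check.

A per-depth ``process="seasonal"`` mode instead draws that layer from a
purely seasonal autoregressive process — useful for probing when a direct
time-series baseline should beat the water-balance route — and a
``disturbance_ar1`` coefficient adds serially correlated noise to probe
robustness to misspecification.

Also bundled here are two small published reference tables for a Xilingol
League steppe site: the 21-month driver forecast (Apr 2022–Dec 2023) with
its fitted interception and balance-increment columns, and the matching
depth-resolved moisture forecast.  They serve as worked examples and test
fixtures; the site's historical series are not redistributable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import vegetation
from .interception import InterceptionParams, interception_series
from .timeseries import DriverSet, MonthlySeries, SoilMoistureProfile
from .water_balance import WaterBalanceConfig, delta_beta

__all__ = [
    "DepthScenario",
    "SiteScenario",
    "generate",
    "xilingol_driver_forecast",
    "xilingol_sm_forecast",
    "XILINGOL_GAMMAS",
]

#: published depth coefficients for the Xilingol reference site
XILINGOL_GAMMAS = {10: -0.1069, 40: -0.1357, 100: -0.0652, 200: -0.0018}

#: monthly share of annual precipitation outside June–September; June–
#: September shares are scaled so the summer block carries summer_p_fraction
_WINTER_WEIGHTS = {1: 0.03, 2: 0.05, 3: 0.10, 4: 0.14, 5: 0.22,
                   10: 0.22, 11: 0.16, 12: 0.08}
_SUMMER_WEIGHTS = {6: 0.22, 7: 0.28, 8: 0.28, 9: 0.22}


@dataclass(frozen=True)
class DepthScenario:
    """Generating parameters for one depth layer.

    ``process="balance"`` evolves the layer by the water-balance recursion;
    ``process="seasonal"`` draws a seasonal AR(1) cycle around ``init``
    instead (amplitude ``seasonal_amp`` kg/m3, peak in August).
    """

    gamma: float
    init: float
    alpha: float = 1.0
    noise_sd: float = 0.0
    process: str = "balance"
    seasonal_amp: float = 3.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.init < 0:
            raise ValueError("init must be >= 0")
        if self.process not in ("balance", "seasonal"):
            raise ValueError("process must be 'balance' or 'seasonal'")


def _default_depths() -> dict[int, DepthScenario]:
    # noise decreasing with depth, mirroring the near-constant deep layer
    sds = {10: 0.8, 40: 0.6, 100: 0.5, 200: 0.05}
    inits = {10: 14.6, 40: 42.4, 100: 55.4, 200: 167.2}
    return {d: DepthScenario(gamma=g, init=inits[d], noise_sd=sds[d])
            for d, g in XILINGOL_GAMMAS.items()}


@dataclass(frozen=True)
class SiteScenario:
    """A complete synthetic-site configuration.

    Climate defaults match a temperate semi-arid steppe: about 340 mm of
    precipitation per year with 74.4% falling June–September, soil
    evaporation peaking near 27 mm/month in July and LAI cycling between
    roughly 0.64 and 0.98 m²/m² with an August peak.
    """

    years: int = 10
    start: tuple[int, int] = (2012, 1)
    annual_p: float = 340.0
    summer_p_fraction: float = 0.744
    se_peak: float = 27.0
    se_min: float = 0.6
    lai_range: tuple[float, float] = (0.64, 0.98)
    depth_params: dict[int, DepthScenario] = field(default_factory=_default_depths)
    seed: int = 0
    #: number of trailing months with observed (non-missing) VCR
    vcr_observed_months: int = 21
    #: AR(1) coefficient of the moisture disturbance (0 = white noise)
    disturbance_ar1: float = 0.0
    balance: WaterBalanceConfig = field(default_factory=WaterBalanceConfig)
    k: float = 1.0

    def __post_init__(self) -> None:
        if self.years < 3:
            raise ValueError("need at least 3 years")
        if not 0 < self.summer_p_fraction < 1:
            raise ValueError("summer_p_fraction must be in (0, 1)")
        if not -1 < self.disturbance_ar1 < 1:
            raise ValueError("disturbance_ar1 must be in (-1, 1)")


def _monthly_p_means(sc: SiteScenario) -> np.ndarray:
    mu = np.zeros(12)
    for m, w in _SUMMER_WEIGHTS.items():
        mu[m - 1] = sc.annual_p * sc.summer_p_fraction * w
    for m, w in _WINTER_WEIGHTS.items():
        mu[m - 1] = sc.annual_p * (1 - sc.summer_p_fraction) * w
    return mu


def generate(sc: SiteScenario) -> tuple[DriverSet, SoilMoistureProfile, dict]:
    """Draw one synthetic site record.

    Returns the driver set (VCR missing except its trailing observed
    window), the multi-depth moisture profile, and a ground-truth record
    holding the generating parameters, the complete VCR series and the
    realised balance-increment series.
    """
    rng = np.random.default_rng(sc.seed)
    n = sc.years * 12
    months = np.array([(sc.start[1] - 1 + t) % 12 + 1 for t in range(n)])

    # precipitation: gamma draws around the monthly climatology; low-mean
    # months are exactly zero half the time (dry months), with the mean
    # preserved by doubling the wet-case draw
    mu = _monthly_p_means(sc)[months - 1]
    shape = 1.5
    p = np.where(mu > 0, rng.gamma(shape, np.maximum(mu, 1e-12) / shape), 0.0)
    dry = (mu <= 3.0) & (rng.uniform(size=n) < 0.5)
    wet_boost = (mu <= 3.0) & ~dry
    p = np.where(dry, 0.0, np.where(wet_boost, 2 * p, p))

    # soil evaporation: July-peaked cosine plus noise, floored just above 0
    se_cycle = sc.se_min + (sc.se_peak - sc.se_min) * 0.5 * (
        1 + np.cos(2 * np.pi * (months - 7) / 12))
    se = np.maximum(se_cycle * np.exp(rng.normal(0, 0.12, n)), 0.05)

    # LAI: August-peaked cosine plus small noise; NDVI a monotone affine map
    lo, hi = sc.lai_range
    lai_cycle = lo + (hi - lo) * 0.5 * (1 + np.cos(2 * np.pi * (months - 8) / 12))
    lai = np.maximum(lai_cycle + rng.normal(0, 0.01, n), 0.01)
    ndvi = 0.62 * lai - 0.20

    vcr_model = vegetation.steppe_vcr_model()
    vcr_true = vegetation.predict_vcr(vcr_model, ndvi)
    vcr_obs = np.full(n, np.nan)
    k_obs = min(sc.vcr_observed_months, n)
    if k_obs:
        vcr_obs[n - k_obs:] = vcr_true[n - k_obs:]

    mk = lambda name, unit, vals, **kw: MonthlySeries(name, unit, sc.start,
                                                      vals, **kw)
    drivers = DriverSet(
        p=mk("P", "mm/month", p), se=mk("SE", "mm/month", se),
        ndvi=mk("NDVI", "dimensionless", ndvi), lai=mk("LAI", "m2/m2", lai),
        vcr=mk("VCR", "fraction", vcr_obs, allow_missing=True),
    )

    ic_params = InterceptionParams.from_lai(float(lai.max()), k=sc.k)
    ic = interception_series(mk("VCR", "fraction", vcr_true), drivers.p,
                             ic_params)
    dbeta = np.array([delta_beta(pp, ss, ii, sc.balance)
                      for pp, ss, ii in zip(p, se, ic.values)])

    series = {}
    for depth, dp in sorted(sc.depth_params.items()):
        eps = rng.normal(0, dp.noise_sd, n) if dp.noise_sd > 0 else np.zeros(n)
        if sc.disturbance_ar1:
            for t in range(1, n):
                eps[t] += sc.disturbance_ar1 * eps[t - 1]
        beta = np.empty(n)
        if dp.process == "seasonal":
            cyc = dp.seasonal_amp * np.cos(2 * np.pi * (months - 8) / 12)
            e = np.zeros(n)
            for t in range(n):
                e[t] = 0.6 * (e[t - 1] if t else 0.0) + eps[t]
            beta = np.maximum(dp.init + cyc + e, 0.0)
        else:
            beta[0] = max(dp.init + eps[0], 0.0)
            for t in range(1, n):
                beta[t] = max(dp.alpha * beta[t - 1] + dp.gamma * dbeta[t]
                              + eps[t], 0.0)
        series[depth] = mk(f"SM{depth}", "kg/m3", beta)

    profile = SoilMoistureProfile(depths=tuple(sorted(sc.depth_params)),
                                  series=series)
    truth = {
        "scenario": sc,
        "depth_params": dict(sc.depth_params),
        "vcr_true": mk("VCR", "fraction", vcr_true),
        "dbeta": mk("dbeta", "dimensionless", dbeta),
        "ic_params": ic_params,
    }
    return drivers, profile, truth


# ---------------------------------------------------------------------------
# published reference tables (Xilingol League steppe site)

# year, month, SE, P, LAI, VCR, ICstore, dbeta — 21-month driver forecast
_DRIVER_TABLE = [
    (2022, 4, 10.8614, 0.0000, 0.7270, 0.0140, 0.0000, -10.8614),
    (2022, 5, 18.3533, 65.4249, 0.7390, 0.0319, 0.0452, -16.2177),
    (2022, 6, 23.1401, 77.9889, 0.8270, 0.0919, 0.1304, -20.6709),
    (2022, 7, 27.0137, 89.3870, 0.9640, 0.2348, 0.3332, -24.3674),
    (2022, 8, 17.4328, 69.7163, 0.9830, 0.2893, 0.4106, -15.5195),
    (2022, 9, 13.1105, 81.2433, 0.8470, 0.1724, 0.2447, -10.6471),
    (2022, 10, 8.8015, 64.5582, 0.7380, 0.0582, 0.0825, -6.7321),
    (2022, 11, 2.3674, 230.9857, 0.7100, 0.0102, 0.0144, 5.3177),
    (2022, 12, 0.9876, 125.7876, 0.6480, 0.0007, 0.0010, 3.2044),
    (2023, 1, 0.6344, 257.7069, 0.6364, 0.0059, 0.0083, 7.9474),
    (2023, 2, 0.7005, 292.5912, 0.6507, 0.0021, 0.0030, 9.0495),
    (2023, 3, 4.5560, 88.0504, 0.7168, 0.0120, 0.0170, -1.6379),
    (2023, 4, 9.9031, 57.6033, 0.7270, 0.0186, 0.0264, -8.0093),
    (2023, 5, 18.0552, 83.1367, 0.7390, 0.0420, 0.0596, -15.3435),
    (2023, 6, 23.0474, 83.1367, 0.8270, 0.1080, 0.1532, -20.4294),
    (2023, 7, 26.9849, 83.1367, 0.9640, 0.2814, 0.3992, -24.6129),
    (2023, 8, 17.4238, 83.1367, 0.9830, 0.3535, 0.5016, -15.1542),
    (2023, 9, 13.1078, 83.1367, 0.8470, 0.2137, 0.3033, -10.6398),
    (2023, 10, 8.8006, 83.1367, 0.7380, 0.0701, 0.0994, -6.1288),
    (2023, 11, 2.3671, 83.1367, 0.7100, 0.0078, 0.0111, 0.3930),
    (2023, 12, 0.9875, 83.1367, 0.6480, 0.0002, 0.0002, 1.7835),
]

# year, month, SM10, SM40, SM100, SM200 — matching moisture forecast
_SM_TABLE = [
    (2022, 4, 15.12, 52.35, 94.11, 164.44),
    (2022, 5, 15.59, 52.23, 96.09, 164.32),
    (2022, 6, 15.91, 51.57, 98.81, 164.15),
    (2022, 7, 16.12, 50.45, 102.15, 163.94),
    (2022, 8, 14.94, 47.35, 105.22, 163.71),
    (2022, 9, 14.28, 45.48, 107.23, 163.56),
    (2022, 10, 13.76, 44.12, 108.58, 163.47),
    (2022, 11, 12.41, 41.95, 108.80, 163.42),
    (2022, 12, 12.68, 42.66, 108.14, 163.47),
    (2023, 1, 12.21, 42.26, 107.35, 163.51),
    (2023, 2, 12.16, 42.73, 106.09, 163.59),
    (2023, 3, 13.39, 44.89, 105.43, 163.66),
    (2023, 4, 14.05, 45.63, 106.09, 163.63),
    (2023, 5, 14.76, 46.00, 107.77, 163.54),
    (2023, 6, 15.17, 45.49, 110.40, 163.38),
    (2023, 7, 15.42, 44.46, 113.73, 163.17),
    (2023, 8, 14.18, 41.26, 116.81, 162.94),
    (2023, 9, 13.56, 39.46, 118.79, 162.79),
    (2023, 10, 12.98, 38.02, 120.09, 162.70),
    (2023, 11, 12.22, 36.66, 120.58, 162.65),
    (2023, 12, 12.08, 36.50, 120.43, 162.65),
]


@dataclass(frozen=True)
class DriverForecastTable:
    """The bundled 21-month driver forecast with its fitted interception
    (``ic``) and balance-increment (``dbeta``) columns."""

    se: MonthlySeries
    p: MonthlySeries
    lai: MonthlySeries
    vcr: MonthlySeries
    ic: MonthlySeries
    dbeta: MonthlySeries

    def __len__(self) -> int:
        return len(self.p)


def xilingol_driver_forecast() -> DriverForecastTable:
    """The published 21-month (Apr 2022–Dec 2023) driver forecast table."""
    a = np.array([r[2:] for r in _DRIVER_TABLE])
    start = (2022, 4)
    return DriverForecastTable(
        se=MonthlySeries("SE", "mm/month", start, a[:, 0]),
        p=MonthlySeries("P", "mm/month", start, a[:, 1]),
        lai=MonthlySeries("LAI", "m2/m2", start, a[:, 2]),
        vcr=MonthlySeries("VCR", "fraction", start, a[:, 3]),
        ic=MonthlySeries("ICstore", "mm/month", start, a[:, 4]),
        dbeta=MonthlySeries("dbeta", "dimensionless", start, a[:, 5]),
    )


def xilingol_sm_forecast() -> dict[int, MonthlySeries]:
    """The published depth-resolved moisture forecast matching
    :func:`xilingol_driver_forecast`, by depth in cm."""
    a = np.array([r[2:] for r in _SM_TABLE])
    start = (2022, 4)
    return {d: MonthlySeries(f"SM{d}", "kg/m3", start, a[:, i])
            for i, d in enumerate((10, 40, 100, 200))}
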