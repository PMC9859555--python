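"""Monthly soil-water balance and the depth-resolved recursive forecaster.

The monthly soil-moisture increment at the surface is the simplified
balance

    Δβ_t = s·P_t − SE_t − IC_t,

where P is precipitation, SE soil evaporation, IC canopy interception and
the runoff and groundwater-exchange terms are assumed to cancel (flat
steppe terrain, vertical water exchange dominant).  The factor ``s``
(``precip_scale``, default 1/30) rescales monthly precipitation before it
enters the balance; scale 1 recovers the unscaled balance.

Soil moisture at depth ``h`` then evolves by the linear recursion

    β_{h,t+1} = α·β_{h,t} + γ_h·Δβ_t,

with adjustment coefficient α (default 1) and a per-depth coefficient γ_h
that translates the surface increment into a change at depth.  γ_h is
estimated by regressing observed one-month soil-moisture changes on Δβ
through the origin; an optional joint mode estimates (α, γ_h) together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from . import vegetation
from .interception import InterceptionParams, interception_series
from .timeseries import DriverSet, MonthlySeries, SoilMoistureProfile

__all__ = [
    "WaterBalanceConfig",
    "DepthModel",
    "PipelineStageError",
    "delta_beta",
    "delta_beta_series",
    "fit_depth_model",
    "forecast_recursive",
    "model_a_pipeline",
    "ModelAConfig",
    "ModelAResult",
]


@dataclass(frozen=True)
class WaterBalanceConfig:
    """Configuration of the simplified balance.

    ``precip_scale`` multiplies precipitation before evaporation and
    interception are subtracted.  The runoff and groundwater assumption
    flags are fixed true in this release: those terms are identically zero.
    """

    precip_scale: float = 1.0 / 30.0
    assume_zero_runoff: bool = True
    assume_zero_groundwater: bool = True

    def __post_init__(self) -> None:
        if not self.precip_scale > 0:
            raise ValueError("precip_scale must be > 0")
        if not (self.assume_zero_runoff and self.assume_zero_groundwater):
            raise NotImplementedError(
                "nonzero runoff/groundwater terms are not supported"
            )


@dataclass(frozen=True)
class DepthModel:
    """Per-depth recursion parameters (α, γ_h) with γ's significance level."""

    depth_cm: int
    gamma: float
    alpha: float = 1.0
    gamma_p: float = float("nan")
    gamma_se: float = float("nan")

    def __post_init__(self) -> None:
        if self.depth_cm <= 0:
            raise ValueError("depth_cm must be positive")
        if np.isfinite(self.gamma_p) and not 0 <= self.gamma_p <= 1:
            raise ValueError("gamma_p must be a probability")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def delta_beta(p: float, se: float, ic: float,
               cfg: WaterBalanceConfig = WaterBalanceConfig()) -> float:
    """Monthly soil-moisture increment from the simplified balance."""
    if p < 0 or se < 0 or ic < 0:
        raise ValueError("p, se and ic must all be >= 0")
    return cfg.precip_scale * p - se - ic


def delta_beta_series(
    drivers: DriverSet,
    params: InterceptionParams,
    cfg: WaterBalanceConfig = WaterBalanceConfig(),
) -> MonthlySeries:
    """Balance increment series for a driver set with complete VCR.

    Interception is computed from the driver VCR and P with ``params``;
    the result is a dimensionless monthly increment series named ``dbeta``.
    """
    if not np.isfinite(drivers.vcr.values).all():
        raise ValueError("VCR has missing values; fill it before the balance")
    ic = interception_series(drivers.vcr, drivers.p, params)
    vals = np.array([
        delta_beta(p, se, icv, cfg)
        for p, se, icv in zip(drivers.p.values, drivers.se.values, ic.values)
    ])
    return MonthlySeries("dbeta", "dimensionless", drivers.p.start, vals)


def fit_depth_model(
    sm: MonthlySeries,
    dbeta: MonthlySeries,
    depth_cm: int | None = None,
    estimate_alpha: bool = False,
) -> DepthModel:
    """Estimate the depth coefficient from observed history.

    The increment for month ``t`` drives the change into month ``t`` (the
    same alignment the recursive forecaster uses), so the default mode
    regresses the observed one-month change ``β_t − β_{t−1}`` on ``Δβ_t``
    through the origin (α fixed at 1) and reports γ̂ with its two-sided
    t-test p-value.  With ``estimate_alpha=True`` the level ``β_t`` is
    regressed jointly on ``(β_{t−1}, Δβ_t)`` giving (α̂, γ̂).
    """
    if sm.start != dbeta.start or len(sm) != len(dbeta):
        raise ValueError("soil-moisture and dbeta series are not aligned")
    n = len(sm)
    if n < 4:
        raise ValueError(f"need at least 4 months to fit, got {n}")
    if np.ptp(dbeta.values) == 0:
        raise np.linalg.LinAlgError("constant dbeta series: singular fit")
    depth = depth_cm if depth_cm is not None else _depth_from_name(sm.name)
    y = sm.values[1:]
    x = dbeta.values[1:]
    if estimate_alpha:
        X = np.column_stack([sm.values[:-1], x])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        dof = len(y) - 2
        s2 = resid @ resid / dof if dof > 0 else np.nan
        cov = s2 * np.linalg.inv(X.T @ X)
        se_g = float(np.sqrt(cov[1, 1]))
        t = coef[1] / se_g if se_g > 0 else np.inf
        p = float(2 * scipy.stats.t.sf(abs(t), dof)) if dof > 0 else 0.0
        return DepthModel(depth, float(coef[1]), alpha=float(coef[0]),
                          gamma_p=p, gamma_se=se_g)
    dy = y - sm.values[:-1]
    sxx = float(x @ x)
    gamma = float(x @ dy) / sxx
    resid = dy - gamma * x
    dof = len(dy) - 1
    s2 = float(resid @ resid) / dof
    se_g = np.sqrt(s2 / sxx)
    if se_g > 0:
        p = float(2 * scipy.stats.t.sf(abs(gamma / se_g), dof))
    else:  # noise-free data: the coefficient is exact
        p = 0.0 if gamma != 0 else 1.0
    return DepthModel(depth, gamma, alpha=1.0, gamma_p=p, gamma_se=float(se_g))


def _depth_from_name(name: str) -> int:
    if name.startswith("SM") and name[2:].isdigit():
        return int(name[2:])
    return 1  # unknown depth; positive placeholder


def forecast_recursive(
    beta0: float, dbeta_forecast: MonthlySeries, model: DepthModel
) -> MonthlySeries:
    """Iterate β_{t} = α·β_{t−1} + γ·Δβ_t from the last observed moisture.

    The increment for month ``t`` steps the moisture into month ``t``, so
    the output covers exactly the months of ``dbeta_forecast``.  Values are
    floored at 0 (moisture is physically nonnegative).
    """
    if beta0 < 0:
        raise ValueError("initial soil moisture must be >= 0")
    if len(dbeta_forecast) < 1:
        raise ValueError("empty forecast horizon")
    out = np.empty(len(dbeta_forecast))
    beta = beta0
    for i, db in enumerate(dbeta_forecast.values):
        beta = max(model.alpha * beta + model.gamma * db, 0.0)
        out[i] = beta
    return MonthlySeries(f"SM{model.depth_cm}", "kg/m3",
                         dbeta_forecast.start, out)


@dataclass(frozen=True)
class ModelAConfig:
    """Configuration for the full water-balance forecasting pipeline."""

    balance: WaterBalanceConfig = field(default_factory=WaterBalanceConfig)
    k: float = 1.0
    #: "window-max": one ICmax from the maximum LAI of the window;
    #: "per-month": ICmax recomputed from each month's LAI.
    icmax_mode: str = "window-max"
    estimate_alpha: bool = False
    #: fixed VCR calibration; None selects one from the observed pairs
    vcr_model: "vegetation.PolynomialModel | None" = None
    #: stepwise SARIMA search limits for the driver forecasts
    max_p: int = 5
    max_q: int = 5
    max_P: int = 2
    max_Q: int = 2

    def __post_init__(self) -> None:
        if self.icmax_mode not in ("window-max", "per-month"):
            raise ValueError("icmax_mode must be 'window-max' or 'per-month'")


@dataclass(frozen=True)
class ModelAResult:
    """Everything the hybrid pipeline produced, stage by stage."""

    forecasts: dict[int, MonthlySeries]
    depth_models: dict[int, DepthModel]
    driver_forecasts: dict[str, MonthlySeries]
    dbeta_history: MonthlySeries
    dbeta_forecast: MonthlySeries
    ic_params: InterceptionParams
    vcr_model: "vegetation.PolynomialModel"


def _interception_for(vcr, p, lai, k, mode) -> tuple[MonthlySeries, InterceptionParams]:
    params = InterceptionParams.from_lai(float(np.max(lai.values)), k=k)
    if mode == "window-max":
        return interception_series(vcr, p, params), params
    from .interception import interception_flow
    vals = np.array([
        interception_flow(c, pp, InterceptionParams.from_lai(l, k=k))
        for c, pp, l in zip(vcr.values, p.values, lai.values)
    ])
    return MonthlySeries("ICstore", "mm/month", p.start, vals), params


def model_a_pipeline(
    drivers: DriverSet,
    sm_profile: SoilMoistureProfile,
    horizon: int,
    cfg: ModelAConfig = ModelAConfig(),
) -> ModelAResult:
    """Run the hybrid water-balance forecast end to end.

    Stages: (1) fill VCR from NDVI; (2) forecast the four drivers
    ``horizon`` months ahead with seasonal ARIMA; (3) interception from the
    forecast cover and precipitation, ICmax from the forecast-window LAI;
    (4) balance increment forecast; (5) per-depth (α, γ) fits on history;
    (6) recursive per-depth forecasts from the last observed moisture.
    """
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    from . import sarima  # deferred: keeps module import cheap

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as e:  # tag failures with their stage
                raise PipelineStageError(name, e) from e
        return deco

    @stage("fill-vcr")
    def vcr_filled():
        return vegetation.fill_vcr(drivers.ndvi, drivers.vcr, model=cfg.vcr_model)

    vcr_hist, vcr_model = vcr_filled

    @stage("forecast-drivers")
    def driver_fc():
        out = {}
        limits = dict(max_p=cfg.max_p, max_q=cfg.max_q,
                      max_P=cfg.max_P, max_Q=cfg.max_Q)
        for name, series in (("P", drivers.p), ("SE", drivers.se),
                             ("LAI", drivers.lai), ("VCR", vcr_hist)):
            fitted = sarima.auto_fit(series, **limits)
            fc = sarima.forecast(fitted, horizon).point
            vals = np.clip(fc.values, 0.0, None)
            if series.unit == "fraction":
                vals = np.clip(vals, 0.0, 1.0)
            out[name] = fc.with_values(vals)
        return out

    @stage("interception")
    def ic():
        return _interception_for(driver_fc["VCR"], driver_fc["P"],
                                 driver_fc["LAI"], cfg.k, cfg.icmax_mode)

    ic_fc, ic_params = ic

    @stage("dbeta")
    def dbetas():
        hist_ic, _ = _interception_for(vcr_hist, drivers.p, drivers.lai,
                                       cfg.k, cfg.icmax_mode)
        hist = MonthlySeries("dbeta", "dimensionless", drivers.p.start, np.array([
            delta_beta(p, se, icv, cfg.balance)
            for p, se, icv in zip(drivers.p.values, drivers.se.values,
                                  hist_ic.values)
        ]))
        fc = MonthlySeries("dbeta", "dimensionless", driver_fc["P"].start,
                           np.array([
            delta_beta(p, se, icv, cfg.balance)
            for p, se, icv in zip(driver_fc["P"].values,
                                  driver_fc["SE"].values, ic_fc.values)
        ]))
        return hist, fc

    dbeta_hist, dbeta_fc = dbetas

    @stage("fit-depths")
    def fits():
        return {
            d: fit_depth_model(sm_profile.series[d], dbeta_hist, depth_cm=d,
                               estimate_alpha=cfg.estimate_alpha)
            for d in sm_profile.depths
        }

    @stage("forecast-depths")
    def fcs():
        out = {}
        for d in sm_profile.depths:
            beta0 = float(sm_profile.series[d].values[-1])
            out[d] = forecast_recursive(beta0, dbeta_fc, fits[d])
        return out

    return ModelAResult(
        forecasts=fcs, depth_models=fits, driver_forecasts=driver_fc,
        dbeta_history=dbeta_hist, dbeta_forecast=dbeta_fc,
        ic_params=ic_params, vcr_model=vcr_model,
    )
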