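"""Seasonal ARIMA fitting, automatic order selection and forecasting.

This powers both halves of the package: the meteorological/vegetation
drivers are extrapolated with seasonal ARIMA before entering the water
balance, and the same machinery fit directly to a soil-moisture record is
the pure time-series baseline.

Order selection follows the usual automatic recipe: the ordinary
differencing order ``d`` comes from repeated KPSS testing, the seasonal
order ``D`` from an STL-based seasonal-strength heuristic, and the ARMA
orders from a stepwise neighbourhood search minimising AIC (ties broken by
BIC, then by total order), with an exhaustive mode for verification.
Estimation uses the state-space (innovations) likelihood via
:class:`statsmodels.tsa.statespace.sarimax.SARIMAX`.

Coefficient convention: AR parameters φ are those of the polynomial
``1 − φ₁B − ... − φ_pB^p`` and MA parameters θ those of
``1 + θ₁B + ... + θ_qB^q`` (statsmodels convention), so a printed factor
``(1 − 0.5852B)`` acting on the innovations is stored as ``ma = (−0.5852,)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.stats
from statsmodels.tools.sm_exceptions import ConvergenceWarning, ValueWarning
from statsmodels.tsa.seasonal import STL
from statsmodels.tsa.statespace.sarimax import SARIMAX
from statsmodels.tsa.stattools import kpss

from .timeseries import MonthlySeries, add_months

__all__ = [
    "SarimaSpec",
    "FittedSarima",
    "ForecastResult",
    "auto_fit",
    "forecast",
    "ljung_box",
    "apply_published_model",
    "model_b_pipeline",
    "steppe_sm_models",
    "difference",
    "undifference",
]

logger = logging.getLogger(__name__)

KPSS_ALPHA = 0.05
MAX_D = 2
MAX_SEASONAL_D = 1
SEASONAL_STRENGTH_THRESHOLD = 0.64


@dataclass(frozen=True)
class SarimaSpec:
    """Orders and coefficients of a (fitted or published) seasonal ARIMA.

    ``order`` is (p, d, q), ``seasonal_order`` (P, D, Q) at ``period``.
    Coefficient vectors follow the statsmodels sign convention (module
    docstring).  ``sigma2`` is the innovation variance.
    """

    order: tuple[int, int, int]
    seasonal_order: tuple[int, int, int] = (0, 0, 0)
    period: int = 12
    ar: tuple[float, ...] = ()
    ma: tuple[float, ...] = ()
    sar: tuple[float, ...] = ()
    sma: tuple[float, ...] = ()
    const: float = 0.0
    sigma2: float = float("nan")
    aic: float = float("nan")
    bic: float = float("nan")

    def __post_init__(self) -> None:
        p, d, q = self.order
        P, D, Q = self.seasonal_order
        if min(p, d, q, P, D, Q) < 0:
            raise ValueError("orders must be nonnegative")
        if (P or D or Q) and self.period < 2:
            raise ValueError("period must be >= 2 for a seasonal model")
        for name, vec, k in (("ar", self.ar, p), ("ma", self.ma, q),
                             ("sar", self.sar, P), ("sma", self.sma, Q)):
            if len(vec) != k:
                raise ValueError(f"{name} has {len(vec)} coefficients, order is {k}")
        if np.isfinite(self.sigma2) and self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")

    @property
    def total_order(self) -> int:
        return sum(self.order[::2]) + sum(self.seasonal_order[::2])


@dataclass
class FittedSarima:
    """A fitted model: its spec, the training series and the statsmodels
    results object (``None`` for a degenerate constant-series fit)."""

    spec: SarimaSpec
    series: MonthlySeries
    results: object | None = None
    degenerate: bool = False
    #: (spec, aic) for every converged candidate examined during selection
    search_trace: list = field(default_factory=list)

    @property
    def resid(self) -> np.ndarray:
        if self.degenerate or self.results is None:
            return np.zeros(len(self.series))
        # drop the burn-in residuals consumed by differencing
        d = self.spec.order[1] + self.spec.seasonal_order[1] * self.spec.period
        return np.asarray(self.results.resid)[d:]

    def ljung_box_p(self, lags: int = 12) -> float:
        """Portmanteau white-noise p-value of the residuals."""
        if self.degenerate:
            return 1.0
        df = min(len(self.spec.ar) + len(self.spec.ma)
                 + len(self.spec.sar) + len(self.spec.sma), lags - 1)
        return ljung_box(self.resid, lags=lags, fitted_df=df)[1]


@dataclass(frozen=True)
class ForecastResult:
    """Point forecast with Gaussian interval bounds at ``level``."""

    point: MonthlySeries
    lower: MonthlySeries
    upper: MonthlySeries
    level: float = 0.95

    def __post_init__(self) -> None:
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")
        if not (np.all(self.lower.values <= self.point.values + 1e-9)
                and np.all(self.point.values <= self.upper.values + 1e-9)):
            raise ValueError("interval bounds must bracket the point forecast")


# ---------------------------------------------------------------------------
# differencing helpers

def difference(y, d: int = 0, D: int = 0, period: int = 12) -> np.ndarray:
    """Apply ``D`` seasonal then ``d`` ordinary differences."""
    z = np.asarray(y, dtype=float)
    for _ in range(D):
        z = z[period:] - z[:-period]
    for _ in range(d):
        z = np.diff(z)
    return z


def undifference(z, head, d: int = 0, D: int = 0, period: int = 12) -> np.ndarray:
    """Invert :func:`difference` given the ``d + D*period`` leading values
    of the original series; the round trip is exact.

    ``head`` must be the first ``d + D*period`` values of the original
    series; the return value is the full reconstructed series (head
    included).
    """
    head = np.asarray(head, dtype=float)
    z = np.asarray(z, dtype=float)
    need = d + D * period
    if len(head) != need:
        raise ValueError(f"need exactly {need} leading values, got {len(head)}")
    if need == 0:
        return z
    # Stage 1: undo the d ordinary differences.  The seasonally (but not
    # ordinarily) differenced series w has first d values difference(head,
    # 0, D); rebuild w in full by repeated cumulative summation.
    w_head = difference(head, d=0, D=D, period=period)  # length d
    x = z
    for i in range(d - 1, -1, -1):
        lead = difference(w_head, d=i)[0]
        x = np.concatenate([[lead], lead + np.cumsum(x)])
    # Stage 2: undo the D seasonal differences, outermost last.
    for j in range(D - 1, -1, -1):
        lead = difference(head, d=0, D=j, period=period)[:period]
        full = np.concatenate([lead, x])
        for t in range(period, len(full)):
            full[t] = full[t - period] + full[t]
        x = full
    return x


# ---------------------------------------------------------------------------
# order selection

def _select_d(y: np.ndarray, max_d: int = MAX_D) -> int:
    """Smallest d for which the d-times-differenced series passes KPSS."""
    z = np.asarray(y, dtype=float)
    for d in range(max_d + 1):
        if np.ptp(z) == 0:
            return d
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # p-value outside table bounds
            try:
                _, p, *_ = kpss(z, regression="c", nlags="auto")
            except (ValueError, OverflowError):
                return d
        if p >= KPSS_ALPHA:
            return d
        z = np.diff(z)
    return max_d


def _seasonal_strength(y: np.ndarray, period: int) -> float:
    """STL-based seasonal strength: 1 − Var(remainder)/Var(seasonal+remainder)."""
    if len(y) < 2 * period + 4 or np.ptp(y) == 0:
        return 0.0
    try:
        res = STL(np.asarray(y, float), period=period, robust=True).fit()
    except Exception:
        return 0.0
    detr = res.seasonal + res.resid
    v = np.var(detr)
    if v == 0:
        return 0.0
    return max(0.0, 1.0 - np.var(res.resid) / v)


def _select_D(y: np.ndarray, period: int) -> int:
    return 1 if _seasonal_strength(y, period) >= SEASONAL_STRENGTH_THRESHOLD else 0


def _fit_candidate(y, order, seasonal_order, period, trend):
    sorder = (*seasonal_order[:1], seasonal_order[1], seasonal_order[2], period) \
        if any(seasonal_order) else (0, 0, 0, 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        warnings.simplefilter("ignore", category=ValueWarning)
        warnings.simplefilter("ignore", category=RuntimeWarning)
        warnings.simplefilter("ignore", category=UserWarning)
        try:
            mod = SARIMAX(y, order=order, seasonal_order=sorder, trend=trend,
                          enforce_stationarity=True, enforce_invertibility=True)
            res = mod.fit(disp=False, maxiter=200, method="lbfgs")
            if not res.mle_retvals.get("converged", True):
                res2 = mod.fit(disp=False, maxiter=500, method="powell")
                if res2.mle_retvals.get("converged", True):
                    res = res2
                else:
                    logger.info("candidate %s%s did not converge; skipped",
                                order, sorder)
                    return None
        except (np.linalg.LinAlgError, ValueError) as e:
            logger.info("candidate %s%s failed (%s); skipped", order, sorder, e)
            return None
    if not np.isfinite(res.aic):
        return None
    return res


def _spec_from_results(res, order, seasonal_order, period) -> SarimaSpec:
    names = res.model.param_names
    par = dict(zip(names, np.asarray(res.params, float)))
    ar = tuple(par[f"ar.L{i}"] for i in range(1, order[0] + 1))
    ma = tuple(par[f"ma.L{i}"] for i in range(1, order[2] + 1))
    sar = tuple(par[f"ar.S.L{period * i}"] for i in range(1, seasonal_order[0] + 1))
    sma = tuple(par[f"ma.S.L{period * i}"] for i in range(1, seasonal_order[2] + 1))
    return SarimaSpec(
        order=order, seasonal_order=seasonal_order, period=period,
        ar=ar, ma=ma, sar=sar, sma=sma,
        const=float(par.get("intercept", 0.0)),
        sigma2=float(par.get("sigma2", np.nan)),
        aic=float(res.aic), bic=float(res.bic),
    )


def _rank_key(spec_aic_bic):
    spec, aic, bic = spec_aic_bic
    return (round(aic, 8), round(bic, 8), spec.total_order)


def auto_fit(
    series: MonthlySeries,
    max_p: int = 5,
    max_q: int = 5,
    max_P: int = 2,
    max_Q: int = 2,
    period: int = 12,
    d: int | None = None,
    D: int | None = None,
    stepwise: bool = True,
) -> FittedSarima:
    """Automatically select and fit a seasonal ARIMA for a monthly series.

    ``d`` and ``D`` may be forced; otherwise ``d`` is chosen by repeated
    KPSS testing at the 5% level (max 2) and ``D`` by seasonal strength.
    The (p, q, P, Q) search is stepwise by default (seeded at (2,2,1,1)
    with single-coordinate neighbourhood moves, auto.arima style);
    ``stepwise=False`` searches the full grid.  Candidates that fail to
    converge are skipped, never fatal.  A constant series yields a flagged
    degenerate white-noise fit with ``sigma2 = 0``.
    """
    y = np.asarray(series.values, dtype=float)
    n = len(y)
    if np.ptp(y) == 0:
        spec = SarimaSpec((0, 0, 0), (0, 0, 0), period, const=float(y[0]),
                          sigma2=0.0, aic=-np.inf, bic=-np.inf)
        return FittedSarima(spec, series, results=None, degenerate=True)

    seasonal_ok = period >= 2 and n >= 2 * period + 4
    if not seasonal_ok:
        max_P = max_Q = 0
        D = 0
    if D is None:
        D = _select_D(y, period)
    D = min(D, MAX_SEASONAL_D)
    if d is None:
        d = _select_d(difference(y, 0, D, period))
    trend = "c" if d + D == 0 else None

    # candidates must leave a few degrees of freedom
    def admissible(p, q, P, Q):
        k = p + q + P + Q + (1 if trend else 0)
        eff_n = n - d - D * period
        return k + 2 <= eff_n

    cache: dict[tuple, tuple] = {}

    def evaluate(p, q, P, Q):
        key = (p, q, P, Q)
        if key in cache:
            return cache[key]
        if not admissible(p, q, P, Q):
            cache[key] = None
            return None
        res = _fit_candidate(y, (p, d, q), (P, D, Q), period, trend)
        if res is None:
            cache[key] = None
            return None
        spec = _spec_from_results(res, (p, d, q), (P, D, Q), period)
        cache[key] = (spec, res)
        return cache[key]

    if stepwise:
        seeds = [(2, 2, 1, 1), (0, 0, 0, 0), (1, 0, 1, 0), (0, 1, 0, 1)]
        seeds = [(min(p, max_p), min(q, max_q), min(P, max_P), min(Q, max_Q))
                 for p, q, P, Q in seeds]
        best = None
        for s in dict.fromkeys(seeds):
            r = evaluate(*s)
            if r and (best is None
                      or _rank_key((r[0], r[0].aic, r[0].bic))
                      < _rank_key((best[0], best[0].aic, best[0].bic))):
                best = r
        if best is None:
            raise RuntimeError("no seed candidate converged")
        improved = True
        while improved:
            improved = False
            p0, q0 = best[0].order[0], best[0].order[2]
            P0, Q0 = best[0].seasonal_order[0], best[0].seasonal_order[2]
            moves = [(p0 + dp, q0 + dq, P0 + dP, Q0 + dQ)
                     for dp, dq, dP, dQ in (
                         (1, 0, 0, 0), (-1, 0, 0, 0), (0, 1, 0, 0), (0, -1, 0, 0),
                         (0, 0, 1, 0), (0, 0, -1, 0), (0, 0, 0, 1), (0, 0, 0, -1),
                         (1, 1, 0, 0), (-1, -1, 0, 0), (0, 0, 1, 1), (0, 0, -1, -1))]
            for p, q, P, Q in moves:
                if not (0 <= p <= max_p and 0 <= q <= max_q
                        and 0 <= P <= max_P and 0 <= Q <= max_Q):
                    continue
                r = evaluate(p, q, P, Q)
                if r and (_rank_key((r[0], r[0].aic, r[0].bic))
                          < _rank_key((best[0], best[0].aic, best[0].bic))):
                    best = r
                    improved = True
                    break
    else:
        best = None
        for p in range(max_p + 1):
            for q in range(max_q + 1):
                for P in range(max_P + 1):
                    for Q in range(max_Q + 1):
                        r = evaluate(p, q, P, Q)
                        if r and (best is None
                                  or _rank_key((r[0], r[0].aic, r[0].bic))
                                  < _rank_key((best[0], best[0].aic, best[0].bic))):
                            best = r
        if best is None:
            raise RuntimeError("no candidate converged")

    trace = [(v[0], v[0].aic) for v in cache.values() if v is not None]
    return FittedSarima(best[0], series, results=best[1], search_trace=trace)


# ---------------------------------------------------------------------------
# forecasting

def forecast(fitted: FittedSarima, horizon: int, level: float = 0.95
             ) -> ForecastResult:
    """Point forecasts and Gaussian intervals ``horizon`` months ahead."""
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    start = add_months(fitted.series.end, 1)
    name = fitted.series.name
    unit = fitted.series.unit
    if fitted.degenerate:
        const = np.full(horizon, fitted.spec.const)
        s = MonthlySeries(name, unit, start, const, validate_range=False)
        return ForecastResult(point=s, lower=s, upper=s, level=level)
    pred = fitted.results.get_forecast(horizon)
    mean = np.asarray(pred.predicted_mean, float)
    ci = np.asarray(pred.conf_int(alpha=1 - level), float)

    def mk(vals, suffix=""):
        return MonthlySeries(name + suffix, unit, start, vals,
                             validate_range=False)

    return ForecastResult(point=mk(mean), lower=mk(ci[:, 0], "_lo"),
                          upper=mk(ci[:, 1], "_hi"), level=level)


def ljung_box(residuals, lags: int = 12, fitted_df: int = 0
              ) -> tuple[float, float]:
    """Portmanteau test that residual autocorrelations 1..lags are zero.

    Q = n(n+2)·Σ_k ρ̂_k²/(n−k), referred to χ² with ``lags − fitted_df``
    degrees of freedom, where ``fitted_df`` is the number of estimated ARMA
    coefficients.  Residuals are taken as mean-zero (no demeaning).
    """
    e = np.asarray(residuals, dtype=float)
    n = len(e)
    if lags >= n:
        raise ValueError(f"lags ({lags}) must be < n ({n})")
    if fitted_df >= lags:
        raise ValueError("fitted_df must be < lags")
    denom = float(e @ e)
    if denom == 0:
        return 0.0, 1.0
    ks = np.arange(1, lags + 1)
    rho = np.array([float(e[k:] @ e[:-k]) / denom for k in ks])
    q = n * (n + 2) * float(np.sum(rho**2 / (n - ks)))
    p = float(scipy.stats.chi2.sf(q, lags - fitted_df))
    return q, p


def apply_published_model(
    spec: SarimaSpec, history: MonthlySeries, horizon: int, level: float = 0.95
) -> ForecastResult:
    """Forecast ``history`` with a fixed published coefficient set.

    The coefficient polynomials are applied through the state-space filter
    without re-estimation; only the innovation variance is concentrated out
    of the likelihood (it scales the intervals, not the point forecasts).
    """
    y = np.asarray(history.values, dtype=float)
    p, d, q = spec.order
    P, D, Q = spec.seasonal_order
    need = d + D * spec.period + max(p + P * spec.period, q + Q * spec.period) + 1
    if len(y) < need:
        raise ValueError(
            f"history of length {len(y)} too short to initialise the "
            f"recursion; need at least {need} months"
        )
    sorder = (P, D, Q, spec.period) if (P or D or Q) else (0, 0, 0, 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mod = SARIMAX(y, order=spec.order, seasonal_order=sorder, trend=None,
                      enforce_stationarity=False, enforce_invertibility=False,
                      concentrate_scale=True)
        params = np.array(spec.ar + spec.ma + spec.sar + spec.sma, dtype=float)
        res = mod.filter(params)
        pred = res.get_forecast(horizon)
        mean = np.asarray(pred.predicted_mean, float)
        ci = np.asarray(pred.conf_int(alpha=1 - level), float)
    start = add_months(history.end, 1)

    def mk(vals, suffix=""):
        return MonthlySeries(history.name + suffix, history.unit, start, vals,
                             validate_range=False)

    return ForecastResult(point=mk(mean), lower=mk(ci[:, 0], "_lo"),
                          upper=mk(ci[:, 1], "_hi"), level=level)


def steppe_sm_models() -> dict[int, SarimaSpec]:
    """Published seasonal-ARIMA soil-moisture baselines for a semi-arid
    steppe site, by depth in cm.

    These are pure moving-average forms; the printed 200 cm model appears
    typographically garbled (duplicated polynomial factors) and is not
    shipped.  The 40 cm entry stores the product of its printed factors
    expanded to a single MA(3) polynomial.
    """
    return {
        10: SarimaSpec((0, 0, 1), (0, 1, 1), 12,
                       ma=(-0.5852,), sma=(-0.7593,)),
        40: SarimaSpec((0, 1, 3), (0, 0, 2), 12,
                       ma=(-2.0546, 1.2787131, -0.2220525),
                       sma=(-0.4081, -0.2313)),
        100: SarimaSpec((0, 1, 1), (0, 0, 0), 12, ma=(0.5308,)),
    }


def model_b_pipeline(profile, horizon: int, level: float = 0.95, **limits
                     ) -> dict[int, tuple[FittedSarima, ForecastResult]]:
    """Fit and forecast each depth's soil-moisture series independently."""
    out = {}
    for depth in profile.depths:
        fitted = auto_fit(profile.series[depth], **limits)
        out[depth] = (fitted, forecast(fitted, horizon, level))
    return out
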