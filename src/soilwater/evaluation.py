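"""Forecast error metrics and the two-model comparison protocol.

Metrics are the usual quartet — MSE, RMSE, MAE and MAPE (in percent) — on
a held-out test window.  The default protocol trains on everything through
December 2020 and tests from January 2021 onward; :func:`compare_models`
tabulates metric × depth × model and flags the per-cell minimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .timeseries import MonthlySeries, SoilMoistureProfile

__all__ = ["ErrorReport", "score", "compare_models", "DEFAULT_SPLIT"]

#: first month of the default test window
DEFAULT_SPLIT = (2021, 1)


@dataclass(frozen=True)
class ErrorReport:
    """The four error metrics over n test months (MAPE in percent, or None
    when some actual value is zero)."""

    n: int
    mse: float
    rmse: float
    mae: float
    mape: float | None

    def __post_init__(self) -> None:
        if min(self.mse, self.rmse, self.mae) < 0:
            raise ValueError("metrics must be nonnegative")
        if abs(self.rmse - np.sqrt(self.mse)) > 1e-9 * max(1.0, self.rmse):
            raise ValueError("rmse must equal sqrt(mse)")


def score(actual: MonthlySeries, predicted: MonthlySeries) -> ErrorReport:
    """Error metrics of ``predicted`` against ``actual`` over their common
    (identical) months.

    MAPE requires every actual value nonzero; otherwise it is reported as
    ``None`` with a warning and the remaining metrics are still computed.
    """
    if actual.start != predicted.start or len(actual) != len(predicted):
        raise ValueError(
            f"actual ({actual.start}, n={len(actual)}) and predicted "
            f"({predicted.start}, n={len(predicted)}) are not aligned"
        )
    y = np.asarray(actual.values, float)
    yhat = np.asarray(predicted.values, float)
    err = yhat - y
    mse = float(np.mean(err**2))
    mae = float(np.mean(np.abs(err)))
    if np.any(y == 0):
        warnings.warn("actual series contains zeros; MAPE undefined",
                      stacklevel=2)
        mape = None
    else:
        mape = float(100.0 * np.mean(np.abs(err / y)))
    return ErrorReport(n=len(y), mse=mse, rmse=float(np.sqrt(mse)),
                       mae=mae, mape=mape)


def compare_models(
    actual_profile: SoilMoistureProfile,
    forecasts: dict[str, dict[int, MonthlySeries]],
    rel_tol: float = 1e-9,
) -> pd.DataFrame:
    """Tabulate error metrics per (metric, depth, model) and flag the best.

    ``forecasts`` maps model name → depth → forecast series aligned with the
    actuals.  Every model must supply every depth.  Returns a long-format
    frame with columns ``metric, depth_cm, model, value, is_best``; ties
    (within ``rel_tol`` relative tolerance) are all flagged.
    """
    models = sorted(forecasts)
    if not models:
        raise ValueError("no forecasts supplied")
    for m in models:
        missing = [d for d in actual_profile.depths if d not in forecasts[m]]
        if missing:
            raise ValueError(f"model {m!r} missing forecasts for depths {missing}")
    rows = []
    for depth in actual_profile.depths:
        reports = {m: score(actual_profile.series[depth], forecasts[m][depth])
                   for m in models}
        for metric in ("mse", "rmse", "mae", "mape"):
            vals = {m: getattr(reports[m], metric) for m in models}
            present = {m: v for m, v in vals.items() if v is not None}
            best = min(present.values()) if present else None
            for m in models:
                v = vals[m]
                is_best = (v is not None and best is not None
                           and v <= best * (1 + rel_tol) + rel_tol)
                rows.append({"metric": metric, "depth_cm": depth, "model": m,
                             "value": np.nan if v is None else v,
                             "is_best": bool(is_best)})
    return pd.DataFrame(rows)


def best_model_by_depth(table: pd.DataFrame, metric: str = "rmse"
                        ) -> dict[int, str]:
    """Winner of each depth under one metric (first alphabetically on ties)."""
    sub = table[(table.metric == metric) & table.is_best]
    return {int(d): sorted(g.model)[0] for d, g in sub.groupby("depth_cm")}
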