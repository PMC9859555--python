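"""Vegetation coverage rate (VCR) from NDVI by polynomial regression.

Ground observations of the coverage fraction are typically sparse compared
with the NDVI record, so the missing months are filled from a polynomial
fit of VCR on NDVI.  Candidate degrees 1-3 are fitted by OLS and the
selected model is the one with the largest adjusted R² among candidates
whose slope coefficients are all significant at the 5% level.

A fixed published coefficient set for a semi-arid steppe site,

    VCR = 0.008 - 0.894·NDVI + 5.827·NDVI² - 5.778·NDVI³,

ships as :func:`steppe_vcr_model` so the pipeline can be run exactly as
calibrated for that site without its original coverage observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .timeseries import MonthlySeries

__all__ = [
    "PolynomialModel",
    "fit_vcr_polynomial",
    "select_vcr_model",
    "predict_vcr",
    "steppe_vcr_model",
    "fill_vcr",
]

SIGNIFICANCE_LEVEL = 0.05


@dataclass(frozen=True)
class PolynomialModel:
    """A fitted polynomial VCR = c + b1·NDVI + ... + b_degree·NDVI^degree.

    ``coefficients`` is ordered (c, b1, ..., b_degree).  ``coef_p`` holds the
    two-sided t-test p-value of each coefficient; ``selected`` records
    whether the model passed the all-slopes-significant selection rule.
    """

    degree: int
    coefficients: tuple[float, ...]
    adj_r2: float
    f_test_p: float
    coef_p: tuple[float, ...]
    selected: bool = True

    def __post_init__(self) -> None:
        if len(self.coefficients) != self.degree + 1:
            raise ValueError("coefficient count must equal degree + 1")
        if np.isfinite(self.adj_r2) and self.adj_r2 > 1 + 1e-12:
            raise ValueError("adjusted R² cannot exceed 1")

    def __call__(self, ndvi, clip: bool = True):
        return predict_vcr(self, ndvi, clip=clip)


def _design(ndvi: np.ndarray, degree: int) -> np.ndarray:
    return np.vander(ndvi, degree + 1, increasing=True)


def fit_vcr_polynomial(ndvi, vcr, degree: int) -> PolynomialModel:
    """OLS fit of VCR on powers 1..degree of NDVI.

    Reports adjusted R², the overall F-test p-value and per-coefficient
    two-sided t-test p-values.  Requires at least ``degree + 2`` pairs so a
    residual degree of freedom remains.
    """
    if degree not in (1, 2, 3):
        raise ValueError(f"degree must be 1, 2 or 3, got {degree}")
    x = np.asarray(ndvi, dtype=float)
    y = np.asarray(vcr, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("ndvi and vcr must be 1-D and paired")
    if len(x) < degree + 2:
        raise ValueError(f"need at least {degree + 2} pairs for degree {degree}")
    if np.ptp(x) == 0:
        raise np.linalg.LinAlgError("NDVI values are all identical: singular fit")
    X = _design(x, degree)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design: singular fit")
    res = sm.OLS(y, X).fit()
    return PolynomialModel(
        degree=degree,
        coefficients=tuple(float(c) for c in res.params),
        adj_r2=float(res.rsquared_adj),
        f_test_p=float(res.f_pvalue),
        coef_p=tuple(float(p) for p in res.pvalues),
    )


def select_vcr_model(ndvi, vcr, alpha: float = SIGNIFICANCE_LEVEL
                     ) -> tuple[PolynomialModel, list[PolynomialModel]]:
    """Fit degrees 1-3 and select by adjusted R² subject to significance.

    A candidate is admissible when every slope coefficient (the intercept is
    exempt) has p < ``alpha``.  Among admissible candidates the one with the
    largest adjusted R² wins.  If no candidate is admissible the highest
    adjusted-R² model is returned with ``selected=False``.

    Returns ``(best, candidates)`` where ``candidates`` is the full degree
    1-3 comparison table.
    """
    candidates = [fit_vcr_polynomial(ndvi, vcr, d) for d in (1, 2, 3)]
    admissible = [m for m in candidates
                  if all(p < alpha for p in m.coef_p[1:])]
    if admissible:
        best = max(admissible, key=lambda m: m.adj_r2)
    else:
        best = max(candidates, key=lambda m: m.adj_r2)
        best = PolynomialModel(best.degree, best.coefficients, best.adj_r2,
                               best.f_test_p, best.coef_p, selected=False)
    return best, candidates


def predict_vcr(model: PolynomialModel, ndvi, clip: bool = True):
    """Evaluate the polynomial at ``ndvi``; clip to the physical range [0, 1].

    ``clip=False`` returns the raw polynomial value (useful when comparing
    against published uncut regression output).
    """
    x = np.asarray(ndvi, dtype=float)
    out = np.polynomial.polynomial.polyval(x, np.asarray(model.coefficients))
    if clip:
        out = np.clip(out, 0.0, 1.0)
    return float(out) if np.isscalar(ndvi) else out


def steppe_vcr_model() -> PolynomialModel:
    """The published cubic NDVI→VCR calibration for a semi-arid steppe site.

    The fit statistics (adjusted R² 0.864) are those reported with the
    calibration; the underlying 21 coverage observations are not
    redistributable, so this model is a fixed constant, not refittable.
    """
    return PolynomialModel(
        degree=3,
        coefficients=(0.008, -0.894, 5.827, -5.778),
        adj_r2=0.864,
        f_test_p=0.000,
        coef_p=(float("nan"), 0.05, 0.01, 0.05),
    )


def fill_vcr(ndvi: MonthlySeries, vcr: MonthlySeries,
             model: PolynomialModel | None = None,
             min_obs: int = 8) -> tuple[MonthlySeries, PolynomialModel]:
    """Fill missing VCR cells from NDVI.

    If ``model`` is given it is used directly.  Otherwise a model is
    selected from the observed (NDVI, VCR) pairs when at least ``min_obs``
    are available; with fewer observations the fixed steppe calibration is
    used.  Observed cells are kept as-is.
    """
    obs = np.isfinite(vcr.values)
    if model is None:
        if obs.sum() >= min_obs:
            model, _ = select_vcr_model(ndvi.values[obs], vcr.values[obs])
        else:
            model = steppe_vcr_model()
    filled = vcr.values.copy()
    filled[~obs] = predict_vcr(model, ndvi.values[~obs])
    return vcr.with_values(filled, allow_missing=False), model
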