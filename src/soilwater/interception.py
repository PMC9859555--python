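"""Canopy interception of rainfall.

Interception storage saturates with precipitation: with cover fraction
``cp``, maximum storage ``ICmax`` (mm) and a vegetation-density correction
``k`` the monthly interception flow is

    IC = cp · ICmax · (1 − exp(−k·P / ICmax)).

``ICmax`` is estimated from the leaf area index by the empirical quadratic

    ICmax = 0.935 + 0.498·LAI − 0.00575·LAI²  (mm),

which is increasing over the physically relevant LAI range (its vertex sits
near LAI 43.3, far beyond grassland canopies).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .timeseries import MonthlySeries

__all__ = [
    "InterceptionParams",
    "intercept_max",
    "interception_flow",
    "interception_series",
]


@dataclass(frozen=True)
class InterceptionParams:
    """Interception parameters: maximum storage (mm) and density correction.

    ``k`` defaults to 1 (dense-canopy correction disabled); ``ic_max`` is
    usually computed from LAI via :func:`intercept_max`.
    """

    ic_max: float
    k: float = 1.0

    def __post_init__(self) -> None:
        if not self.ic_max >= 0:
            raise ValueError(f"ic_max must be >= 0, got {self.ic_max}")
        if not self.k > 0:
            raise ValueError(f"k must be > 0, got {self.k}")

    @classmethod
    def from_lai(cls, lai: float, k: float = 1.0) -> "InterceptionParams":
        return cls(ic_max=intercept_max(lai), k=k)


def intercept_max(lai: float) -> float:
    """Maximum canopy interception storage (mm) from leaf area index."""
    if not lai >= 0:
        raise ValueError(f"LAI must be >= 0, got {lai}")
    return 0.935 + 0.498 * lai - 0.00575 * lai**2


def interception_flow(cp: float, p: float, params: InterceptionParams) -> float:
    """Monthly interception flow (mm/month) for cover fraction ``cp`` and
    precipitation ``p``.

    Saturates at ``cp * ic_max`` as precipitation grows; returns 0 for a
    bare canopy (``ic_max == 0``).
    """
    if not 0 <= cp <= 1:
        raise ValueError(f"cover fraction must be in [0, 1], got {cp}")
    if not p >= 0:
        raise ValueError(f"precipitation must be >= 0, got {p}")
    if params.ic_max == 0:
        return 0.0
    return cp * params.ic_max * (1.0 - math.exp(-params.k * p / params.ic_max))


def interception_series(
    vcr: MonthlySeries, p: MonthlySeries, params: InterceptionParams
) -> MonthlySeries:
    """Elementwise interception flow for aligned cover and precipitation."""
    if vcr.start != p.start or len(vcr) != len(p):
        raise ValueError("VCR and P series are not aligned")
    vals = np.array(
        [interception_flow(c, pp, params) for c, pp in zip(vcr.values, p.values)]
    )
    return MonthlySeries("ICstore", "mm/month", p.start, vals)
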