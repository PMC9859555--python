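"""Month-indexed series containers and CSV I/O.

Everything downstream (interception, water balance, SARIMA forecasting)
operates on gap-free monthly series.  A :class:`MonthlySeries` is a named,
unit-tagged vector of one value per consecutive calendar month; the site
record bundles the meteorological/vegetation drivers (:class:`DriverSet`)
and the multi-depth soil-moisture observations
(:class:`SoilMoistureProfile`).

The canonical on-disk exchange format is a wide CSV with one row per month:
``year,month,P,SE,NDVI,LAI,VCR,SM10,SM40,...``.  Only the vegetation
coverage rate (VCR) may have empty cells — in field records it is typically
a short, recent subset that is later filled by regression on NDVI; a gap in
any other column is an error rather than something to impute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MonthlySeries",
    "DriverSet",
    "SoilMoistureProfile",
    "MalformedInputError",
    "month_range",
    "add_months",
    "read_site_csv",
    "write_site_csv",
    "split_by_date",
]

#: units recognised on a series
VALID_UNITS = ("mm/month", "kg/m3", "dimensionless", "m2/m2", "fraction")

#: units whose values must be nonnegative
NONNEGATIVE_UNITS = ("mm/month", "kg/m3")


class MalformedInputError(ValueError):
    """Raised when an input table violates the monthly-record contract."""


def add_months(start: tuple[int, int], n: int) -> tuple[int, int]:
    """Return the (year, month) pair ``n`` months after ``start``."""
    y, m = start
    k = (y * 12 + (m - 1)) + n
    return k // 12, k % 12 + 1


def month_range(start: tuple[int, int], n: int) -> list[tuple[int, int]]:
    """List of ``n`` consecutive (year, month) pairs beginning at ``start``."""
    return [add_months(start, i) for i in range(n)]


@dataclass(frozen=True)
class MonthlySeries:
    """A gap-free monthly series of one variable.

    Parameters
    ----------
    name : str
        Variable identifier (``"P"``, ``"SE"``, ``"SM40"``, ...).
    unit : str
        One of ``mm/month``, ``kg/m3``, ``dimensionless``, ``m2/m2``,
        ``fraction``.
    start : (int, int)
        First (year, month) of the series.
    values : array-like of float
        One value per consecutive month.  All values must be finite unless
        ``allow_missing`` is set (used only for partially observed VCR),
        and nonnegative for ``mm/month`` / ``kg/m3`` units.
    """

    name: str
    unit: str
    start: tuple[int, int]
    values: np.ndarray
    allow_missing: bool = False
    #: disable the nonnegativity check for model-derived quantities (e.g.
    #: forecast interval bounds) that may legitimately cross zero
    validate_range: bool = True

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "start", (int(self.start[0]), int(self.start[1])))
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        if vals.ndim != 1 or len(vals) < 1:
            raise ValueError("values must be a nonempty 1-D sequence")
        if not 1 <= self.start[1] <= 12:
            raise ValueError(f"start month must be in 1..12, got {self.start[1]}")
        finite = np.isfinite(vals)
        if not self.allow_missing and not finite.all():
            bad = month_range(self.start, len(vals))[int(np.argmin(finite))]
            raise ValueError(f"{self.name}: non-finite value at {bad[0]}-{bad[1]:02d}")
        if (self.validate_range and self.unit in NONNEGATIVE_UNITS
                and np.any(vals[finite] < 0)):
            bad = np.flatnonzero(finite & (vals < 0))[0]
            ym = add_months(self.start, int(bad))
            raise ValueError(
                f"{self.name}: negative value {vals[bad]} at {ym[0]}-{ym[1]:02d} "
                f"not allowed for unit {self.unit}"
            )

    def __len__(self) -> int:
        return len(self.values)

    @property
    def end(self) -> tuple[int, int]:
        """Last (year, month) covered by the series."""
        return add_months(self.start, len(self) - 1)

    def months(self) -> list[tuple[int, int]]:
        return month_range(self.start, len(self))

    def index_of(self, month: tuple[int, int]) -> int:
        """Position of ``month`` within the series; raises if outside."""
        y, m = month
        i = (y * 12 + m - 1) - (self.start[0] * 12 + self.start[1] - 1)
        if not 0 <= i < len(self):
            raise IndexError(
                f"{y}-{m:02d} outside series span "
                f"{self.start[0]}-{self.start[1]:02d}..{self.end[0]}-{self.end[1]:02d}"
            )
        return i

    def with_values(self, values: Sequence[float], **kw) -> "MonthlySeries":
        return replace(self, values=np.asarray(values, dtype=float), **kw)

    def to_pandas(self) -> pd.Series:
        """Return the series with a monthly :class:`pandas.PeriodIndex`."""
        idx = pd.period_range(
            start=f"{self.start[0]}-{self.start[1]:02d}", periods=len(self), freq="M"
        )
        return pd.Series(self.values, index=idx, name=self.name)


def _check_aligned(*series: MonthlySeries) -> None:
    s0 = series[0]
    for s in series[1:]:
        if s.start != s0.start or len(s) != len(s0):
            raise ValueError(
                f"series {s.name!r} (start {s.start}, n={len(s)}) not aligned with "
                f"{s0.name!r} (start {s0.start}, n={len(s0)})"
            )


@dataclass(frozen=True)
class DriverSet:
    """Aligned driver series for one site: P, SE, NDVI, LAI and VCR.

    VCR may contain NaN cells (partially observed); the vegetation module
    fills them from NDVI.
    """

    p: MonthlySeries
    se: MonthlySeries
    ndvi: MonthlySeries
    lai: MonthlySeries
    vcr: MonthlySeries

    def __post_init__(self) -> None:
        _check_aligned(self.p, self.se, self.ndvi, self.lai, self.vcr)
        v = self.vcr.values
        obs = np.isfinite(v)
        if np.any((v[obs] < 0) | (v[obs] > 1)):
            raise ValueError("VCR values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.p)

    @property
    def start(self) -> tuple[int, int]:
        return self.p.start


@dataclass(frozen=True)
class SoilMoistureProfile:
    """Soil-moisture series (kg/m3) observed at an increasing set of depths."""

    depths: tuple[int, ...]
    series: dict[int, MonthlySeries] = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = tuple(int(x) for x in self.depths)
        object.__setattr__(self, "depths", d)
        if any(x <= 0 for x in d):
            raise ValueError("depths must be positive")
        if list(d) != sorted(set(d)):
            raise ValueError("depths must be strictly increasing")
        if set(self.series) != set(d):
            raise ValueError("series keys must match depths")
        _check_aligned(*[self.series[x] for x in d])

    def __len__(self) -> int:
        return len(self.series[self.depths[0]])

    @property
    def start(self) -> tuple[int, int]:
        return self.series[self.depths[0]].start


_DRIVER_UNITS = {"P": "mm/month", "SE": "mm/month", "NDVI": "dimensionless",
                 "LAI": "m2/m2", "VCR": "fraction"}


def read_site_csv(path) -> tuple[DriverSet, SoilMoistureProfile]:
    """Read a wide site CSV into aligned driver and soil-moisture structures.

    Expected columns: ``year``, ``month``, the drivers ``P``, ``SE``,
    ``NDVI``, ``LAI``, optionally ``VCR``, and one ``SM<depth>`` column per
    observed depth (e.g. ``SM10``, ``SM40``).  Empty cells are tolerated in
    VCR only.  Months must be consecutive.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    cols = {c.strip(): c for c in df.columns}
    for req in ("year", "month"):
        if req not in cols:
            raise MalformedInputError(f"missing required column {req!r}")
    years = df[cols["year"]].to_numpy(dtype=int)
    months = df[cols["month"]].to_numpy(dtype=int)
    if len(df) < 1:
        raise MalformedInputError("empty file")
    start = (int(years[0]), int(months[0]))
    expect = month_range(start, len(df))
    for i, (y, m) in enumerate(zip(years, months)):
        if (int(y), int(m)) != expect[i]:
            raise MalformedInputError(
                f"gap in month sequence: expected {expect[i][0]}-{expect[i][1]:02d} "
                f"at row {i}, found {y}-{m:02d}"
            )

    def col(name: str, unit: str, allow_missing=False) -> MonthlySeries:
        vals = pd.to_numeric(df[cols[name]], errors="coerce").to_numpy(dtype=float)
        if not allow_missing and not np.isfinite(vals).all():
            i = int(np.argmin(np.isfinite(vals)))
            ym = expect[i]
            raise MalformedInputError(
                f"missing/non-numeric {name} value at {ym[0]}-{ym[1]:02d}"
            )
        try:
            return MonthlySeries(name, unit, start, vals, allow_missing=allow_missing)
        except ValueError as e:
            raise MalformedInputError(str(e)) from e

    for name in ("P", "SE", "NDVI", "LAI"):
        if name not in cols:
            raise MalformedInputError(f"missing required column {name!r}")
    if "VCR" in cols:
        vcr = col("VCR", "fraction", allow_missing=True)
    else:
        vcr = MonthlySeries("VCR", "fraction", start,
                            np.full(len(df), np.nan), allow_missing=True)
    drivers = DriverSet(p=col("P", "mm/month"), se=col("SE", "mm/month"),
                        ndvi=col("NDVI", "dimensionless"),
                        lai=col("LAI", "m2/m2"), vcr=vcr)

    sm_cols = [c for c in cols if c.startswith("SM") and c[2:].isdigit()]
    depths = sorted(int(c[2:]) for c in sm_cols)
    if not depths:
        raise MalformedInputError("no SM<depth> columns found")
    series = {d: col(f"SM{d}", "kg/m3") for d in depths}
    profile = SoilMoistureProfile(depths=tuple(depths), series=series)
    return drivers, profile


def write_site_csv(path, drivers: DriverSet, profile: SoilMoistureProfile) -> None:
    """Write the wide site CSV (inverse of :func:`read_site_csv`)."""
    _check_aligned(drivers.p, profile.series[profile.depths[0]])
    months = drivers.p.months()
    out = pd.DataFrame({"year": [y for y, _ in months],
                        "month": [m for _, m in months]})
    for name, s in (("P", drivers.p), ("SE", drivers.se), ("NDVI", drivers.ndvi),
                    ("LAI", drivers.lai), ("VCR", drivers.vcr)):
        out[name] = s.values
    for d in profile.depths:
        out[f"SM{d}"] = profile.series[d].values
    # repr round-trips doubles exactly; empty cell marks an absent value
    out.to_csv(path, index=False,
               float_format=lambda v: "" if math.isnan(v) else repr(float(v)))


def split_by_date(
    series: MonthlySeries, first_test_month: tuple[int, int]
) -> tuple[MonthlySeries, MonthlySeries]:
    """Split a series into (train, test) with the test part starting at
    ``first_test_month``.

    The boundary must be strictly inside the span, so both parts are
    nonempty, and the concatenation of the parts equals the input.
    """
    i = series.index_of(first_test_month)  # raises IndexError outside span
    if i == 0:
        raise IndexError(
            f"first_test_month {first_test_month} is the series start; "
            "train part would be empty"
        )
    train = series.with_values(series.values[:i], allow_missing=series.allow_missing)
    test = MonthlySeries(series.name, series.unit, first_test_month,
                         series.values[i:], allow_missing=series.allow_missing)
    return train, test
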