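"""Climate series handling: annual aggregation, anomalies, linear trends.

Trend significance uses the Student's t-test on the ordinary least-squares
slope with ``df = n - 2``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClimateSeries",
    "TrendResult",
    "annual_from_monthly",
    "compute_anomaly",
    "linear_trend_test",
    "grid_trend_mask",
    "read_climate_csv",
]

log = logging.getLogger(__name__)


@dataclass
class ClimateSeries:
    """A per-station (or per-grid-cell) climate record.

    ``months`` is None for annual series; otherwise parallel to ``years``.
    Missing values are NaN.
    """

    years: np.ndarray
    values: np.ndarray
    months: np.ndarray | None = None
    units: str = ""
    series_id: str = ""

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.months is not None:
            self.months = np.asarray(self.months, dtype=int)
            key = self.years * 12 + (self.months - 1)
        else:
            key = self.years
        if self.years.size != self.values.size:
            raise ValueError("years and values must be parallel")
        if np.any(np.diff(key) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def is_monthly(self) -> bool:
        return self.months is not None

    def to_frame(self) -> pd.DataFrame:
        data = {"station_id": self.series_id, "year": self.years}
        if self.months is not None:
            data["month"] = self.months
        data["value"] = self.values
        return pd.DataFrame(data)


def read_climate_csv(path: str | Path) -> list[ClimateSeries]:
    """Read ``station_id, year[, month], value`` rows into per-station series."""
    df = pd.read_csv(path)
    out = []
    has_month = "month" in df.columns
    for sid, grp in df.groupby("station_id", sort=False):
        out.append(
            ClimateSeries(
                years=grp["year"].to_numpy(),
                values=grp["value"].to_numpy(),
                months=grp["month"].to_numpy() if has_month else None,
                series_id=str(sid),
            )
        )
    return out


@dataclass
class TrendResult:
    slope: float
    intercept: float
    t_stat: float
    df: int
    p_two_tailed: float
    n_used: int
    exact_fit: bool = False

    @property
    def significant_05(self) -> bool:
        return self.p_two_tailed < 0.05

    @property
    def significant_10(self) -> bool:
        return self.p_two_tailed < 0.1

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Confidence interval for the slope at the given level."""
        if self.t_stat == 0 and self.slope == 0:
            half = 0.0 if self.exact_fit else np.inf
        elif self.exact_fit:
            half = 0.0
        else:
            se = abs(self.slope / self.t_stat) if self.t_stat != 0 else np.inf
            half = stats.t.ppf(0.5 + level / 2, self.df) * se
        return self.slope - half, self.slope + half


def annual_from_monthly(
    series: ClimateSeries,
    statistic: str = "mean",
    max_missing_months: int = 2,
) -> ClimateSeries:
    """Collapse a monthly series to one value per year.

    ``mean`` averages the present months; ``sum`` scales to a full-year
    equivalent (``12 * mean`` of present months), which equals the plain sum
    for complete years.  Years missing more than ``max_missing_months``
    months are dropped with a warning.
    """
    if not series.is_monthly:
        raise ValueError("series is not monthly")
    if series.years.size == 0:
        raise ValueError("empty input")
    if statistic not in ("mean", "sum"):
        raise ValueError(f"unknown statistic '{statistic}'")
    df = pd.DataFrame({"year": series.years, "value": series.values})
    years, values, dropped = [], [], 0
    for year, grp in df.groupby("year"):
        present = grp["value"].dropna()
        missing = 12 - len(present)
        if missing > max_missing_months:
            dropped += 1
            continue
        v = present.mean()
        if statistic == "sum":
            v *= 12.0
        years.append(int(year))
        values.append(float(v))
    if dropped:
        log.warning(
            "annual_from_monthly: dropped %d year(s) with > %d missing months",
            dropped,
            max_missing_months,
        )
    if not years:
        raise ValueError("no complete-enough years in input")
    return ClimateSeries(
        years=np.array(years),
        values=np.array(values),
        units=series.units,
        series_id=series.series_id,
    )


def compute_anomaly(
    series: ClimateSeries, baseline: tuple[int, int] | None = None
) -> ClimateSeries:
    """Subtract the baseline-period mean (default: full period of record)."""
    if baseline is None:
        mask = np.ones_like(series.years, dtype=bool)
    else:
        lo, hi = baseline
        mask = (series.years >= lo) & (series.years <= hi)
    base = series.values[mask]
    base = base[np.isfinite(base)]
    if base.size == 0:
        raise ValueError("baseline period has no data")
    return replace(series, values=series.values - base.mean())


def linear_trend_test(series: ClimateSeries) -> TrendResult:
    """OLS trend of value on year with a two-tailed t-test on the slope.

    ``t = slope / se(slope)`` with ``df = n - 2`` over the non-missing points.
    A perfect non-constant fit is flagged ``exact_fit`` with p = 0; a
    constant series gives slope 0, t 0, p 1.
    """
    ok = np.isfinite(series.values)
    x = series.years[ok].astype(float)
    y = series.values[ok]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 non-missing points")
    xbar, ybar = x.mean(), y.mean()
    sxx = np.sum((x - xbar) ** 2)
    sxy = np.sum((x - xbar) * (y - ybar))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - (intercept + slope * x)
    sse = float(np.sum(resid**2))
    df = n - 2
    scale = max(np.sum(y**2), 1.0)
    if sse <= 1e-12 * scale:  # numerically exact fit
        if slope == 0.0:
            return TrendResult(0.0, intercept, 0.0, df, 1.0, n, exact_fit=True)
        t = np.inf if slope > 0 else -np.inf
        return TrendResult(float(slope), float(intercept), t, df, 0.0, n, exact_fit=True)
    se = np.sqrt(sse / df / sxx)
    t = slope / se
    p = 2 * stats.t.sf(abs(t), df)
    return TrendResult(float(slope), float(intercept), float(t), df, float(p), n)


def grid_trend_mask(
    cells: Iterable[ClimateSeries], alpha: float = 0.1
) -> pd.DataFrame:
    """Per-cell trend with slopes masked where p >= alpha.

    Returns a frame with columns ``slope``, ``p_two_tailed``, ``significant``
    and ``slope_masked`` (NaN where masked); the masked fraction is stored in
    ``frame.attrs['masked_fraction']``.
    """
    rows = []
    for cell in cells:
        res = linear_trend_test(cell)
        rows.append(
            {
                "series_id": cell.series_id,
                "slope": res.slope,
                "p_two_tailed": res.p_two_tailed,
                "significant": res.p_two_tailed < alpha,
            }
        )
    if not rows:
        raise ValueError("no cells supplied")
    df = pd.DataFrame(rows).set_index("series_id")
    df["slope_masked"] = df["slope"].where(df["significant"])
    df.attrs["masked_fraction"] = float(1.0 - df["significant"].mean())
    return df
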