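"""Index construction: standardization, profile scores, composite indices.

The chain is: min-max standardize each indicator across units, orient it so
larger means "more of its contributing factor", average within profiles,
combine profiles with indicator-count weights into the composite LVI and the
three IPCC contributing factors, then score vulnerability as
``(exposure - adaptive_capacity) * sensitivity`` on a -1..1 scale and
classify against thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .aggregate import AESIndicatorTable
from .framework import Factor, Framework, Orientation

__all__ = [
    "StandardizedTable",
    "ProfileScores",
    "FactorScores",
    "VulnerabilityResult",
    "DEFAULT_THRESHOLDS",
    "CLASS_LABELS",
    "standardize",
    "profile_scores",
    "composite_lvi",
    "contributing_factors",
    "lvi_ipcc",
    "classify_vulnerability",
    "area_share_by_class",
    "evaluate",
]

log = logging.getLogger(__name__)

#: (t_low, t_high): score < t_low -> low; < t_high -> moderate; else high.
#: t_low = 0 follows "positive score = highly vulnerable"; t_high chosen so a
#: small positive score reads as moderate.
DEFAULT_THRESHOLDS: tuple[float, float] = (0.0, 0.45)

CLASS_LABELS = ("low", "moderate", "high")


@dataclass
class StandardizedTable:
    """Unit x indicator matrix of standardized values in [0, 1]."""

    values: pd.DataFrame
    bounds: pd.DataFrame  # per-indicator columns: min, max
    oriented: pd.Series  # bool per indicator: True once orientation applied

    @property
    def units(self) -> list[str]:
        return list(self.values.index)


@dataclass
class ProfileScores:
    """Unit x profile matrix of profile means plus the weights behind them.

    ``n_used`` is the per-unit count of non-missing indicators actually
    averaged (equals ``profile_sizes`` when nothing is missing); it is the
    weight used for the composite indices.
    """

    values: pd.DataFrame
    profile_sizes: pd.Series  # N_p: indicators defined per profile
    n_used: pd.DataFrame  # per unit x profile


@dataclass
class FactorScores:
    values: pd.DataFrame  # unit x {exposure, sensitivity, adaptive_capacity}
    indicator_totals: pd.Series  # indicators defined per factor

    @property
    def exposure(self) -> pd.Series:
        return self.values["exposure"]

    @property
    def sensitivity(self) -> pd.Series:
        return self.values["sensitivity"]

    @property
    def adaptive_capacity(self) -> pd.Series:
        return self.values["adaptive_capacity"]


@dataclass
class VulnerabilityResult:
    lvi: pd.Series
    lvi_ipcc: pd.Series
    classes: pd.Series
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS
    factors: FactorScores | None = None


def standardize(
    table: AESIndicatorTable,
    fw: Framework,
    bounds: pd.DataFrame | None = None,
) -> StandardizedTable:
    """Min-max standardize each indicator across units and apply orientation.

    ``I_v = (I_a - I_min) / (I_max - I_min)`` with the min/max taken across
    units (or from ``bounds`` with columns ``min``/``max`` indexed by
    indicator id).  Indicators oriented ``factor_decreasing`` are flipped to
    ``1 - I_v`` afterwards.  A constant column maps to 0 with a warning.
    """
    vals = table.values.astype(float)
    if bounds is None:
        if len(vals.index) < 2:
            raise ValueError(
                "single-unit table cannot be min-max standardized; supply "
                "precomputed bounds"
            )
        lo = vals.min(axis=0)
        hi = vals.max(axis=0)
    else:
        lo = bounds["min"].reindex(vals.columns)
        hi = bounds["max"].reindex(vals.columns)

    out = pd.DataFrame(index=vals.index, columns=vals.columns, dtype=float)
    for col in vals.columns:
        span = hi[col] - lo[col]
        if span == 0:
            log.warning("indicator %s is constant across units; standardized to 0", col)
            out[col] = np.where(vals[col].notna(), 0.0, np.nan)
        else:
            out[col] = (vals[col] - lo[col]) / span
    for ind in fw.indicators:
        if ind.id in out.columns and ind.orientation == Orientation.FACTOR_DECREASING:
            out[ind.id] = 1.0 - out[ind.id]
    return StandardizedTable(
        values=out,
        bounds=pd.DataFrame({"min": lo, "max": hi}),
        oriented=pd.Series(True, index=vals.columns),
    )


def profile_scores(st: StandardizedTable, fw: Framework) -> ProfileScores:
    """Per-unit unweighted mean of each profile's standardized indicators.

    Missing cells are skipped and reduce the recorded per-unit count; a
    profile that is entirely missing for some unit is an error.
    """
    values: dict[str, pd.Series] = {}
    n_used: dict[str, pd.Series] = {}
    sizes: dict[str, int] = {}
    for p in fw.profiles:
        cols = [i.id for i in fw.indicators_for(p.id) if i.id in st.values.columns]
        if not cols:
            raise ValueError(f"profile '{p.id}' has no indicators in the table")
        block = st.values[cols]
        counts = block.notna().sum(axis=1)
        if (counts == 0).any():
            bad = list(block.index[counts == 0])
            raise ValueError(
                f"profile '{p.id}' has all-missing indicators in units {bad}"
            )
        values[p.id] = block.mean(axis=1, skipna=True)
        n_used[p.id] = counts
        sizes[p.id] = len(cols)
    return ProfileScores(
        values=pd.DataFrame(values),
        profile_sizes=pd.Series(sizes, name="N_p"),
        n_used=pd.DataFrame(n_used),
    )


def _weighted_over(ps: ProfileScores, profile_ids: list[str]) -> pd.Series:
    w = ps.n_used[profile_ids]
    v = ps.values[profile_ids]
    return (w * v).sum(axis=1) / w.sum(axis=1)


def composite_lvi(ps: ProfileScores) -> pd.Series:
    """Indicator-count-weighted mean of profile scores (the composite LVI).

    Algebraically identical to the flat mean of all (non-missing)
    standardized indicators of the unit.
    """
    if (ps.profile_sizes < 1).any():
        raise ValueError("every profile needs at least one indicator")
    return _weighted_over(ps, list(ps.values.columns)).rename("LVI")


def contributing_factors(ps: ProfileScores, fw: Framework) -> FactorScores:
    """Combine profile scores into exposure / sensitivity / adaptive capacity.

    Each factor score is the indicator-count-weighted mean of its profiles'
    scores; a single-profile factor equals that profile's score.
    """
    cols: dict[str, pd.Series] = {}
    totals: dict[str, int] = {}
    for factor in Factor:
        pids = [p.id for p in fw.profiles_for(factor) if p.id in ps.values.columns]
        if not pids:
            raise ValueError(f"factor '{factor.value}' has no profiles")
        cols[factor.value] = _weighted_over(ps, pids)
        totals[factor.value] = int(ps.profile_sizes[pids].sum())
    return FactorScores(
        values=pd.DataFrame(cols), indicator_totals=pd.Series(totals)
    )


def lvi_ipcc(fs: FactorScores) -> pd.Series:
    """Vulnerability score ``(E - A) * S``; in [-1, 1] for inputs in [0, 1]."""
    e, a, s = fs.exposure, fs.adaptive_capacity, fs.sensitivity
    if not np.isfinite(pd.concat([e, a, s]).to_numpy()).all():
        raise ValueError("factor scores must be finite")
    return ((e - a) * s).rename("LVI_IPCC")


def classify_vulnerability(
    scores: pd.Series | Mapping[str, float],
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
) -> pd.Series:
    """Map scores to low / moderate / high with left-closed thresholds.

    ``score < t_low`` -> low; ``t_low <= score < t_high`` -> moderate;
    ``score >= t_high`` -> high.
    """
    t_low, t_high = thresholds
    if not t_low < t_high:
        raise ValueError("thresholds must satisfy t_low < t_high")
    s = pd.Series(scores, dtype=float)
    out = pd.Series("moderate", index=s.index, name="class")
    out[s < t_low] = "low"
    out[s >= t_high] = "high"
    return out


def area_share_by_class(
    areas: Mapping[str, float], classes: Mapping[str, str]
) -> dict[str, float]:
    """Percent of total area in each vulnerability class, unrounded.

    The denominator is the sum of *all* supplied areas, so units present in
    ``areas`` but absent from ``classes`` (e.g. unpopulated ones) dilute the
    shares; shares then sum to < 100.
    """
    if not areas:
        raise ValueError("empty area set")
    for u, a in areas.items():
        if a <= 0:
            raise ValueError(f"area for '{u}' must be positive")
    total = float(sum(areas.values()))
    shares: dict[str, float] = {}
    for unit, cls in classes.items():
        if unit not in areas:
            continue
        shares[cls] = shares.get(cls, 0.0) + 100.0 * areas[unit] / total
    return shares


def evaluate(
    table: AESIndicatorTable,
    fw: Framework,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
    bounds: pd.DataFrame | None = None,
) -> tuple[StandardizedTable, ProfileScores, FactorScores, VulnerabilityResult]:
    """Run the full chain on a raw indicator table."""
    st = standardize(table, fw, bounds=bounds)
    ps = profile_scores(st, fw)
    fs = contributing_factors(ps, fw)
    result = VulnerabilityResult(
        lvi=composite_lvi(ps),
        lvi_ipcc=lvi_ipcc(fs),
        classes=classify_vulnerability(lvi_ipcc(fs), thresholds),
        thresholds=thresholds,
        factors=fs,
    )
    return st, ps, fs, result
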