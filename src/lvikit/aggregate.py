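"""Household survey records and their aggregation to unit-level indicators.

Turns per-household responses into the unit x indicator raw-value matrix
that feeds standardization, plus the summary helpers used in report tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .framework import Aggregator, Framework, IndicatorDefinition

__all__ = [
    "DEFAULT_TLU_FACTORS",
    "TLU_FIELD",
    "HouseholdRecord",
    "SurveyDataset",
    "AESIndicatorTable",
    "AggregateResult",
    "compute_tlu",
    "aggregate_indicator",
    "build_indicator_table",
    "all_units_summary",
]

log = logging.getLogger(__name__)

#: Standard tropical-livestock-unit conversion factors (user-overridable).
DEFAULT_TLU_FACTORS: dict[str, float] = {
    "camel": 1.0,
    "cattle": 0.7,
    "horse": 0.8,
    "mule": 0.7,
    "donkey": 0.5,
    "sheep": 0.1,
    "goat": 0.1,
    "pig": 0.2,
    "chicken": 0.01,
}

#: Virtual numeric field: when an indicator sources this field and a record
#: has no explicit response for it, the value is derived from the record's
#: livestock counts via :func:`compute_tlu` with the default factor table.
TLU_FIELD = "tlu"


def compute_tlu(
    livestock: Mapping[str, float],
    factors: Mapping[str, float] | None = None,
) -> float:
    """Species-weighted livestock aggregate: ``sum(count * factor)``."""
    factors = DEFAULT_TLU_FACTORS if factors is None else factors
    total = 0.0
    for species, count in livestock.items():
        if count < 0:
            raise ValueError(f"negative head count for species '{species}'")
        try:
            total += count * factors[species]
        except KeyError:
            raise KeyError(f"no TLU conversion factor for species '{species}'") from None
    return total


@dataclass
class HouseholdRecord:
    household_id: str
    unit_id: str
    responses: dict[str, object] = field(default_factory=dict)
    livestock: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.unit_id:
            raise ValueError(f"record {self.household_id!r}: empty unit_id")
        for k, v in self.responses.items():
            if isinstance(v, float) and not math.isfinite(v):
                raise ValueError(
                    f"record {self.household_id!r}: non-finite response {k}={v}"
                )

    def numeric(self, field_name: str) -> float | None:
        """Numeric response, deriving TLU from livestock when needed."""
        v = self.responses.get(field_name)
        if v is None or v == "":
            if field_name == TLU_FIELD and self.livestock:
                return compute_tlu(self.livestock)
            return None
        return float(v)  # type: ignore[arg-type]

    def categorical(self, field_name: str) -> str | None:
        v = self.responses.get(field_name)
        if v is None or v == "":
            return None
        return str(v)


class SurveyDataset:
    """An ordered collection of household records grouped into units (AES)."""

    def __init__(
        self, records: Iterable[HouseholdRecord], units: list[str] | None = None
    ) -> None:
        self.records: list[HouseholdRecord] = list(records)
        seen: list[str] = []
        for r in self.records:
            if r.unit_id not in seen:
                seen.append(r.unit_id)
        if units is None:
            units = seen
        else:
            unknown = set(seen) - set(units)
            if unknown:
                raise ValueError(f"records reference units not listed: {sorted(unknown)}")
        self.units: list[str] = list(units)

    @property
    def n_by_unit(self) -> pd.Series:
        counts = {u: 0 for u in self.units}
        for r in self.records:
            counts[r.unit_id] += 1
        return pd.Series(counts, name="n")

    def __len__(self) -> int:
        return len(self.records)

    def records_in(self, unit_id: str) -> list[HouseholdRecord]:
        return [r for r in self.records if r.unit_id == unit_id]

    # -- delimited text I/O -------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row: dict[str, object] = {
                "household_id": r.household_id,
                "unit_id": r.unit_id,
            }
            row.update(r.responses)
            for sp, c in r.livestock.items():
                row[f"livestock.{sp}"] = c
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, units: list[str] | None = None) -> "SurveyDataset":
        df = pd.read_csv(path, dtype=object, keep_default_na=False)
        records = []
        livestock_cols = [c for c in df.columns if c.startswith("livestock.")]
        response_cols = [
            c for c in df.columns
            if c not in ("household_id", "unit_id") and not c.startswith("livestock.")
        ]
        for _, row in df.iterrows():
            responses = {}
            for c in response_cols:
                v = row[c]
                if v == "" or v is None:
                    continue
                try:
                    responses[c] = float(v)
                except (TypeError, ValueError):
                    responses[c] = str(v)
            livestock = {}
            for c in livestock_cols:
                v = row[c]
                if v not in ("", None):
                    livestock[c.removeprefix("livestock.")] = int(float(v))
            records.append(
                HouseholdRecord(
                    household_id=str(row["household_id"]),
                    unit_id=str(row["unit_id"]),
                    responses=responses,
                    livestock=livestock,
                )
            )
        return cls(records, units=units)


class AggregateResult(NamedTuple):
    """Per-unit aggregated values and the effective n behind each value."""

    values: pd.Series
    n: pd.Series


def aggregate_indicator(
    ds: SurveyDataset, ind: IndicatorDefinition
) -> AggregateResult:
    """Aggregate one indicator across units.

    ``proportion`` -> 100 * matching / non-missing; ``mean``/``sum`` over
    non-missing numeric responses.  Units with zero non-missing responses get
    a NaN cell and a logged warning.
    """
    if ind.aggregator == Aggregator.PRECOMPUTED:
        raise ValueError(
            f"indicator '{ind.id}' is precomputed; supply its values externally"
        )
    field_name = ind.source_fields[0]
    values: dict[str, float] = {}
    ns: dict[str, int] = {}
    for unit in ds.units:
        recs = ds.records_in(unit)
        if ind.aggregator == Aggregator.PROPORTION:
            obs = [r.categorical(field_name) for r in recs]
            obs = [o for o in obs if o is not None]
            if not obs:
                log.warning("indicator %s: unit %s has no responses", ind.id, unit)
                values[unit], ns[unit] = float("nan"), 0
                continue
            match = sum(1 for o in obs if o == ind.target_category)
            values[unit] = 100.0 * match / len(obs)
            ns[unit] = len(obs)
        else:
            nums = [r.numeric(field_name) for r in recs]
            nums = [x for x in nums if x is not None]
            if not nums:
                log.warning("indicator %s: unit %s has no responses", ind.id, unit)
                values[unit], ns[unit] = float("nan"), 0
                continue
            agg = sum(nums)
            if ind.aggregator == Aggregator.MEAN:
                agg /= len(nums)
            values[unit] = agg
            ns[unit] = len(nums)
    return AggregateResult(
        pd.Series(values, name=ind.id).reindex(ds.units),
        pd.Series(ns, name="n").reindex(ds.units),
    )


@dataclass
class AESIndicatorTable:
    """Unit x indicator matrix of raw indicator values.

    ``values`` is indexed by unit id with one column per indicator id;
    ``provenance`` marks each cell as ``survey`` or ``precomputed``;
    ``n`` is the per-unit sample size.
    """

    values: pd.DataFrame
    n: pd.Series
    provenance: pd.DataFrame

    @property
    def units(self) -> list[str]:
        return list(self.values.index)

    @property
    def indicators(self) -> list[str]:
        return list(self.values.columns)

    def to_csv(self, path: str | Path) -> None:
        self.values.rename_axis("unit_id").to_csv(path)


def _precomputed_frame(
    precomputed: pd.DataFrame | Mapping | None, units: list[str]
) -> pd.DataFrame:
    if precomputed is None:
        return pd.DataFrame(index=units)
    if isinstance(precomputed, pd.DataFrame):
        if set(precomputed.columns) >= {"unit_id", "indicator_id", "value"}:
            return precomputed.pivot(
                index="unit_id", columns="indicator_id", values="value"
            ).reindex(units)
        return precomputed.reindex(units)
    # mapping {indicator_id: {unit_id: value}}
    return pd.DataFrame(precomputed).reindex(units)


def build_indicator_table(
    ds: SurveyDataset,
    fw: Framework,
    precomputed: pd.DataFrame | Mapping | None = None,
) -> AESIndicatorTable:
    """Assemble the full unit x indicator matrix for a framework.

    Every indicator must either aggregate from the survey or appear in
    ``precomputed`` (long form ``unit_id,indicator_id,value`` or wide form
    unit x indicator).  A missing source raises, naming the indicator.
    """
    pre = _precomputed_frame(precomputed, ds.units)
    cols: dict[str, pd.Series] = {}
    prov: dict[str, pd.Series] = {}
    for ind in fw.indicators:
        if ind.aggregator == Aggregator.PRECOMPUTED:
            if ind.id not in pre.columns or pre[ind.id].isna().any():
                raise ValueError(
                    f"indicator '{ind.id}' is precomputed but has no supplied "
                    f"value for every unit"
                )
            cols[ind.id] = pre[ind.id].astype(float)
            prov[ind.id] = pd.Series("precomputed", index=ds.units)
        else:
            res = aggregate_indicator(ds, ind)
            cols[ind.id] = res.values
            prov[ind.id] = pd.Series("survey", index=ds.units)
    values = pd.DataFrame(cols, index=ds.units)
    return AESIndicatorTable(
        values=values,
        n=ds.n_by_unit.reindex(ds.units),
        provenance=pd.DataFrame(prov, index=ds.units),
    )


def all_units_summary(
    row: Iterable[float],
    n: Iterable[float] | None = None,
    mode: str = "unweighted",
) -> float:
    """Cross-unit summary of a per-unit row of values.

    ``unweighted`` is the arithmetic mean of unit values; ``weighted`` is the
    sample-size-weighted mean ``sum(n_i v_i) / sum(n_i)``.  Published "all
    households" columns mix both conventions, so callers should report both.
    """
    vals = np.asarray(list(row), dtype=float)
    if vals.size == 0:
        raise ValueError("empty row")
    if mode == "unweighted":
        return float(np.mean(vals))
    if mode == "weighted":
        if n is None:
            raise ValueError("weighted mode requires per-unit n")
        w = np.asarray(list(n), dtype=float)
        if w.size != vals.size:
            raise ValueError("row and n lengths differ")
        if np.any(w <= 0):
            raise ValueError("weighted mode requires n > 0")
        return float(np.sum(w * vals) / np.sum(w))
    raise ValueError(f"unknown mode '{mode}'")
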