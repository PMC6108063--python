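"""Seeded generators for survey datasets and climate series.

The study's raw survey is not deposited, so a synthetic stand-in with the
same stratified structure (5 units, published per-unit sample sizes and
proportions/means) is generated here.  Within-unit dispersions are synthetic
conventions, not published values.
"""

from __future__ import annotations

import zlib
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator

from .aggregate import HouseholdRecord, SurveyDataset, compute_tlu
from .trends import ClimateSeries

__all__ = [
    "UnitSpec",
    "CategoricalLaw",
    "NumericLaw",
    "LivestockLaw",
    "ClimateLaw",
    "SyntheticSpec",
    "default_choke_spec",
    "load_spec",
    "generate_survey",
    "generate_climate_series",
]


class UnitSpec(BaseModel):
    id: str
    n: int = Field(ge=1)


class CategoricalLaw(BaseModel):
    """Per-unit category probabilities; key ``default`` covers unlisted units."""

    categories: list[str]
    probs: dict[str, list[float]]

    @field_validator("probs")
    @classmethod
    def _check_probs(cls, v: dict[str, list[float]]) -> dict[str, list[float]]:
        for unit, ps in v.items():
            if any(p < 0 or p > 1 for p in ps):
                raise ValueError(f"probabilities for '{unit}' outside [0, 1]")
            if not 0.9 <= sum(ps) <= 1.1:  # published rows carry rounding slack
                # (some published category rows sum to ~93% because rare
                # categories are omitted; probabilities are renormalized)
                raise ValueError(f"probabilities for '{unit}' do not sum to ~1")
        return v

    def for_unit(self, unit: str) -> np.ndarray:
        ps = self.probs.get(unit, self.probs.get("default"))
        if ps is None:
            raise KeyError(f"no probabilities for unit '{unit}' and no default")
        arr = np.asarray(ps, dtype=float)
        return arr / arr.sum()


class NumericLaw(BaseModel):
    """Normal or lognormal law parameterized by the target mean.

    Lognormal spread comes from a coefficient of variation (``cv``); normal
    spread from ``sd``.  Both accept per-unit mappings with a ``default`` key.
    """

    dist: str = "lognormal"
    mean: dict[str, float]
    sd: dict[str, float] | None = None
    cv: float = Field(default=0.5, ge=0)

    @field_validator("dist")
    @classmethod
    def _check_dist(cls, v: str) -> str:
        if v not in ("normal", "lognormal"):
            raise ValueError(f"unknown distribution '{v}'")
        return v

    def params(self, unit: str) -> tuple[float, float]:
        m = self.mean.get(unit, self.mean.get("default"))
        if m is None:
            raise KeyError(f"no mean for unit '{unit}' and no default")
        if self.sd is not None:
            s = self.sd.get(unit, self.sd.get("default", 0.0))
        else:
            s = self.cv * m
        return float(m), float(s)


class LivestockLaw(BaseModel):
    """Poisson head counts per species with a common herd composition.

    Species rates are the composition scaled so the expected TLU matches the
    unit's target mean.
    """

    composition: dict[str, float]
    tlu_mean: dict[str, float]

    def rates(self, unit: str) -> dict[str, float]:
        target = self.tlu_mean.get(unit, self.tlu_mean.get("default"))
        if target is None:
            raise KeyError(f"no TLU mean for unit '{unit}' and no default")
        base = compute_tlu(self.composition)
        scale = target / base
        return {sp: r * scale for sp, r in self.composition.items()}


class ClimateLaw(BaseModel):
    series_id: str
    start_year: int
    n_years: int = Field(ge=3)
    slope: float
    sd: float = Field(ge=0)
    baseline: float = 0.0
    units: str = ""


class SyntheticSpec(BaseModel):
    units: list[UnitSpec]
    categorical: dict[str, CategoricalLaw] = Field(default_factory=dict)
    numeric: dict[str, NumericLaw] = Field(default_factory=dict)
    livestock: LivestockLaw | None = None
    climate: list[ClimateLaw] = Field(default_factory=list)
    seed: int = 0

    @property
    def total_n(self) -> int:
        return sum(u.n for u in self.units)

    def unit_ids(self) -> list[str]:
        return [u.id for u in self.units]


def load_spec(document: Mapping | str | Path) -> SyntheticSpec:
    if isinstance(document, Mapping):
        return SyntheticSpec.model_validate(document)
    text = Path(document).read_text()
    return SyntheticSpec.model_validate(yaml.safe_load(text))


def default_choke_spec() -> SyntheticSpec:
    """The packaged 5-unit spec (n = 87/183/148/284/91, total 793)."""
    path = resources.files("lvikit").joinpath("data", "choke_survey.yaml")
    return load_spec(Path(str(path)))


def _unit_rng(seed: int, unit_id: str) -> np.random.Generator:
    # stable per-unit substream: adding a unit never perturbs the others
    return np.random.default_rng([seed, zlib.crc32(unit_id.encode())])


def generate_survey(spec: SyntheticSpec, seed: int | None = None) -> SurveyDataset:
    """Draw a full survey dataset; deterministic for a fixed seed."""
    seed = spec.seed if seed is None else seed
    records: list[HouseholdRecord] = []
    for unit in spec.units:
        rng = _unit_rng(seed, unit.id)
        n = unit.n
        columns: dict[str, np.ndarray] = {}
        for field_name, law in spec.categorical.items():
            probs = law.for_unit(unit.id)
            idx = rng.choice(len(law.categories), size=n, p=probs)
            columns[field_name] = np.asarray(law.categories, dtype=object)[idx]
        for field_name, law in spec.numeric.items():
            m, s = law.params(unit.id)
            if law.dist == "normal":
                draws = rng.normal(m, s, size=n)
            else:
                if m <= 0:
                    raise ValueError(f"lognormal mean for '{field_name}' must be > 0")
                sigma2 = np.log1p((s / m) ** 2)
                mu = np.log(m) - sigma2 / 2
                draws = rng.lognormal(mu, np.sqrt(sigma2), size=n)
            columns[field_name] = draws
        livestock_draws: dict[str, np.ndarray] = {}
        if spec.livestock is not None:
            for sp, rate in spec.livestock.rates(unit.id).items():
                livestock_draws[sp] = rng.poisson(rate, size=n)
        for i in range(n):
            responses = {k: v[i] for k, v in columns.items()}
            responses = {
                k: (str(v) if isinstance(v, str) else float(v))
                for k, v in responses.items()
            }
            records.append(
                HouseholdRecord(
                    household_id=f"{unit.id}-{i + 1:04d}",
                    unit_id=unit.id,
                    responses=responses,
                    livestock={sp: int(v[i]) for sp, v in livestock_draws.items()},
                )
            )
    return SurveyDataset(records, units=spec.unit_ids())


def generate_climate_series(
    years: int | Sequence[int],
    slope: float,
    sd: float,
    seed: int,
    baseline: float = 0.0,
    start_year: int = 1982,
    series_id: str = "synthetic",
    units: str = "",
) -> ClimateSeries:
    """Linear trend plus Gaussian noise: ``baseline + slope*(t - t0) + N(0, sd)``."""
    if isinstance(years, int):
        yr = np.arange(start_year, start_year + years)
    else:
        yr = np.asarray(years, dtype=int)
    if yr.size < 3:
        raise ValueError("need at least 3 years")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sd, size=yr.size) if sd > 0 else np.zeros(yr.size)
    values = baseline + slope * (yr - yr[0]) + noise
    return ClimateSeries(years=yr, values=values, units=units, series_id=series_id)
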