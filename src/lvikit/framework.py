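"""Indicator -> profile -> contributing-factor framework.

A :class:`Framework` encodes which survey-derived indicators feed which
themed profile, and which IPCC contributing factor (exposure, sensitivity,
adaptive capacity) each profile belongs to.  The packaged default framework
describes the Choke Mountain study setup: 8 profiles and 39 indicators.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping

import yaml
from pydantic import BaseModel, Field, ValidationError

__all__ = [
    "Orientation",
    "Aggregator",
    "Factor",
    "Capital",
    "IndicatorDefinition",
    "ProfileDefinition",
    "Framework",
    "Diagnostic",
    "FrameworkError",
    "load_framework",
    "validate_framework",
    "default_framework",
]


class FrameworkError(ValueError):
    """Raised when a framework document cannot be parsed or validated."""


class Orientation(str, enum.Enum):
    """Whether a larger raw value increases the profile's contributing factor."""

    FACTOR_INCREASING = "factor_increasing"
    FACTOR_DECREASING = "factor_decreasing"


class Aggregator(str, enum.Enum):
    PROPORTION = "proportion"
    MEAN = "mean"
    SUM = "sum"
    PRECOMPUTED = "precomputed"


class Factor(str, enum.Enum):
    EXPOSURE = "exposure"
    SENSITIVITY = "sensitivity"
    ADAPTIVE_CAPACITY = "adaptive_capacity"


class Capital(str, enum.Enum):
    NONE = "none"
    NATURAL = "natural"
    FINANCIAL = "financial"
    PHYSICAL = "physical"
    HUMAN = "human"
    SOCIAL = "social"


class IndicatorDefinition(BaseModel):
    """One indicator: how it is measured and how it pushes its factor."""

    id: str
    label: str = ""
    profile_id: str
    unit: str = ""
    orientation: Orientation
    aggregator: Aggregator
    source_fields: list[str] = Field(default_factory=list)
    #: category counted in the numerator for ``proportion`` indicators
    target_category: str | None = None

    model_config = {"frozen": True}


class ProfileDefinition(BaseModel):
    """A themed indicator group mapped to one contributing factor."""

    id: str
    name: str
    factor: Factor
    capital: Capital = Capital.NONE
    indicator_ids: list[str] = Field(default_factory=list)

    model_config = {"frozen": True}


class Framework(BaseModel):
    profiles: list[ProfileDefinition]
    indicators: list[IndicatorDefinition]
    metadata: str = ""
    schema_version: int = 1

    model_config = {"frozen": True}

    # -- lookups -------------------------------------------------------
    def profile(self, profile_id: str) -> ProfileDefinition:
        for p in self.profiles:
            if p.id == profile_id:
                return p
        raise KeyError(profile_id)

    def indicator(self, indicator_id: str) -> IndicatorDefinition:
        for i in self.indicators:
            if i.id == indicator_id:
                return i
        raise KeyError(indicator_id)

    def indicators_for(self, profile_id: str) -> list[IndicatorDefinition]:
        return [i for i in self.indicators if i.profile_id == profile_id]

    def profiles_for(self, factor: Factor | str) -> list[ProfileDefinition]:
        factor = Factor(factor)
        return [p for p in self.profiles if p.factor == factor]

    @property
    def indicator_ids(self) -> list[str]:
        return [i.id for i in self.indicators]

    def to_dict(self) -> dict[str, Any]:
        """Plain-dict form; ``load_framework`` round-trips it."""
        return {
            "schema_version": self.schema_version,
            "metadata": self.metadata,
            "profiles": [
                {
                    "id": p.id,
                    "name": p.name,
                    "factor": p.factor.value,
                    "capital": p.capital.value,
                }
                for p in self.profiles
            ],
            "indicators": [
                {
                    "id": i.id,
                    "label": i.label,
                    "profile": i.profile_id,
                    "unit": i.unit,
                    "orientation": i.orientation.value,
                    "aggregator": i.aggregator.value,
                    "source_fields": list(i.source_fields),
                    **(
                        {"target_category": i.target_category}
                        if i.target_category is not None
                        else {}
                    ),
                }
                for i in self.indicators
            ],
        }


@dataclass(frozen=True)
class Diagnostic:
    severity: str  # "error" | "warning"
    location: str  # dotted key path into the framework
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.severity}] {self.location}: {self.message}"


def _parse_document(doc: Mapping[str, Any] | str | Path) -> Mapping[str, Any]:
    if isinstance(doc, Mapping):
        return doc
    if isinstance(doc, Path) or (isinstance(doc, str) and "\n" not in doc and doc.endswith((".yaml", ".yml", ".json"))):
        text = Path(doc).read_text()
    else:
        text = str(doc)
    try:
        parsed = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise FrameworkError(f"framework document does not parse: {exc}") from exc
    if not isinstance(parsed, Mapping):
        raise FrameworkError("framework document must be a mapping at top level")
    return parsed


def load_framework(document: Mapping[str, Any] | str | Path) -> Framework:
    """Parse and validate a framework configuration document.

    Accepts a mapping, a YAML/JSON string, or a path to a YAML/JSON file.
    Raises :class:`FrameworkError` naming the offending key path when the
    document is malformed or violates referential integrity.
    """
    doc = _parse_document(document)
    for key in ("profiles", "indicators"):
        if key not in doc:
            raise FrameworkError(f"missing required key '{key}'")

    profiles: list[ProfileDefinition] = []
    for idx, raw in enumerate(doc["profiles"]):
        try:
            profiles.append(
                ProfileDefinition(
                    id=raw["id"],
                    name=raw.get("name", raw["id"]),
                    factor=raw["factor"],
                    capital=raw.get("capital", "none"),
                )
            )
        except (KeyError, ValidationError) as exc:
            raise FrameworkError(f"profiles[{idx}]: {exc}") from exc

    indicators: list[IndicatorDefinition] = []
    for idx, raw in enumerate(doc["indicators"]):
        try:
            indicators.append(
                IndicatorDefinition(
                    id=raw["id"],
                    label=raw.get("label", ""),
                    profile_id=raw.get("profile", raw.get("profile_id")),
                    unit=raw.get("unit", ""),
                    orientation=raw["orientation"],
                    aggregator=raw["aggregator"],
                    source_fields=list(raw.get("source_fields", [])),
                    target_category=raw.get("target_category"),
                )
            )
        except (KeyError, ValidationError) as exc:
            raise FrameworkError(f"indicators[{idx}]: {exc}") from exc

    # attach indicator ids to their profiles in document order
    by_profile: dict[str, list[str]] = {p.id: [] for p in profiles}
    for ind in indicators:
        if ind.profile_id in by_profile:
            by_profile[ind.profile_id].append(ind.id)
    profiles = [
        p.model_copy(update={"indicator_ids": by_profile[p.id]}) for p in profiles
    ]

    fw = Framework(
        profiles=profiles,
        indicators=indicators,
        metadata=str(doc.get("metadata", "")),
        schema_version=int(doc.get("schema_version", 1)),
    )
    # structural errors block loading; factor-coverage gaps are reported by
    # validate_framework but a partial (e.g. single-profile) framework loads
    errors = [
        d
        for d in validate_framework(fw)
        if d.severity == "error" and not d.location.startswith("factors.")
    ]
    if errors:
        raise FrameworkError("; ".join(f"{d.location}: {d.message}" for d in errors))
    return fw


def validate_framework(fw: Framework) -> list[Diagnostic]:
    """Check framework invariants; empty list iff the framework is valid.

    Returns diagnostics instead of raising, so broken frameworks can be
    inspected.
    """
    out: list[Diagnostic] = []
    profile_ids = [p.id for p in fw.profiles]
    seen: set[str] = set()
    for p in profile_ids:
        if p in seen:
            out.append(Diagnostic("error", f"profiles.{p}", "duplicate profile id"))
        seen.add(p)

    seen = set()
    for ind in fw.indicators:
        loc = f"indicators.{ind.id}"
        if ind.id in seen:
            out.append(Diagnostic("error", loc, "duplicate indicator id"))
        seen.add(ind.id)
        if ind.profile_id not in profile_ids:
            out.append(
                Diagnostic(
                    "error", loc, f"references unknown profile '{ind.profile_id}'"
                )
            )
        if ind.aggregator == Aggregator.PROPORTION:
            if len(ind.source_fields) != 1:
                out.append(
                    Diagnostic(
                        "error",
                        loc,
                        "proportion aggregator requires exactly one source field",
                    )
                )
            if ind.target_category is None:
                out.append(
                    Diagnostic(
                        "error", loc, "proportion aggregator requires a target_category"
                    )
                )
        if ind.aggregator != Aggregator.PRECOMPUTED and not ind.source_fields:
            out.append(
                Diagnostic(
                    "error", loc, "survey-aggregated indicator needs source_fields"
                )
            )

    for p in fw.profiles:
        if not fw.indicators_for(p.id):
            out.append(
                Diagnostic("error", f"profiles.{p.id}", "profile has no indicators")
            )
        claimed = set(p.indicator_ids)
        actual = {i.id for i in fw.indicators_for(p.id)}
        if claimed and claimed != actual:
            out.append(
                Diagnostic(
                    "error",
                    f"profiles.{p.id}",
                    "indicator_ids disagree with indicator profile assignments",
                )
            )

    for factor in Factor:
        if not fw.profiles_for(factor):
            out.append(
                Diagnostic(
                    "error",
                    f"factors.{factor.value}",
                    "no profile mapped to this contributing factor",
                )
            )
    return out


def _data_path(name: str) -> Path:
    return Path(str(resources.files("lvikit").joinpath("data", name)))


def default_framework() -> Framework:
    """The packaged Choke Mountain default: 8 profiles, 39 indicators."""
    return load_framework(_data_path("choke_framework.yaml"))
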