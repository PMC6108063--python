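"""Accessors for the small packaged data files."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "data_path",
    "default_precomputed",
    "default_areas",
    "published_indices",
    "published_summaries",
]


def data_path(name: str) -> Path:
    return Path(str(resources.files("lvikit").joinpath("data", name)))


def default_precomputed() -> pd.DataFrame:
    """Unit-level precomputed indicator cells (long form) for the default run."""
    return pd.read_csv(data_path("choke_precomputed.csv"))


def default_areas() -> dict[str, float]:
    df = pd.read_csv(data_path("choke_areas.csv"))
    return dict(zip(df["unit_id"], df["area_km2"].astype(float)))


def published_indices() -> pd.DataFrame:
    """Published per-unit contributing-factor and vulnerability scores."""
    return pd.read_csv(data_path("choke_published_indices.csv")).set_index("unit_id")


def published_summaries() -> dict:
    """Published per-unit summary rows (percentages, means, counts)."""
    return yaml.safe_load(data_path("choke_published_summaries.yaml").read_text())
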