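"""Report-table formatting.

Indices are printed at 2 decimals and percentages at 1 decimal, rounded
half-up to match the published precision.  The "paper" style appends an
Average row of unweighted column means.
"""

from __future__ import annotations

import io
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = ["round_half_up", "format_table", "parse_tidy", "index_table"]

AVERAGE_LABEL = "Average"


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.545 -> 0.55 at 2 d.p.), unlike banker's."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _with_average(df: pd.DataFrame) -> pd.DataFrame:
    numeric = df.select_dtypes(include=[np.number])
    avg = numeric.mean(axis=0)
    out = df.copy()
    out.loc[AVERAGE_LABEL] = avg
    return out


def format_table(
    result: pd.DataFrame,
    style: str = "paper",
    decimals: int = 2,
    footnotes: list[str] | None = None,
) -> str:
    """Render a unit-indexed result frame as text.

    ``paper``: fixed-precision wide table with an appended Average row
    (unweighted column means over the numeric columns).  ``tidy``: long-form
    CSV (``unit,variable,value``) at full precision, re-parsable with
    :func:`parse_tidy`.
    """
    if style == "tidy":
        long = result.rename_axis("unit").reset_index().melt(
            id_vars="unit", var_name="variable", value_name="value"
        )
        buf = io.StringIO()
        long.to_csv(buf, index=False)
        return buf.getvalue()
    if style != "paper":
        raise ValueError(f"unknown style '{style}'")

    table = _with_average(result)
    formatted = table.copy()
    for col in table.columns:
        if pd.api.types.is_numeric_dtype(table[col]):
            formatted[col] = [
                f"{round_half_up(v, decimals):.{decimals}f}" if pd.notna(v) else ""
                for v in table[col]
            ]
        else:
            formatted[col] = ["" if pd.isna(v) else str(v) for v in table[col]]
            formatted.loc[AVERAGE_LABEL, col] = ""
    lines = [formatted.rename_axis("unit").reset_index().to_string(index=False)]
    for note in footnotes or []:
        lines.append(f"note: {note}")
    return "\n".join(lines) + "\n"


def parse_tidy(text: str) -> pd.DataFrame:
    """Invert ``format_table(..., style='tidy')``."""
    long = pd.read_csv(io.StringIO(text))
    wide = long.pivot(index="unit", columns="variable", values="value")
    return wide.rename_axis(None, axis=1).rename_axis(None)


def index_table(
    exposure: pd.Series,
    sensitivity: pd.Series,
    adaptive_capacity: pd.Series,
    lvi: pd.Series | None = None,
    lvi_ipcc: pd.Series | None = None,
    classes: pd.Series | None = None,
) -> pd.DataFrame:
    """Assemble the per-unit index summary frame (one row per unit)."""
    data: dict[str, pd.Series] = {
        "E": exposure,
        "S": sensitivity,
        "A": adaptive_capacity,
    }
    if lvi is not None:
        data["LVI"] = lvi
    if lvi_ipcc is not None:
        data["LVI_IPCC"] = lvi_ipcc
    df = pd.DataFrame(data)
    if classes is not None:
        df["class"] = classes
    return df


def identity_footnote(df: pd.DataFrame, tol: float = 0.005) -> list[str]:
    """Flag rows whose reported score departs from ``(E - A) * S``.

    Published tables can carry scores that do not satisfy the defining
    identity of their own printed factor columns; the mismatch is surfaced
    rather than silently reconciled.
    """
    needed = {"E", "S", "A", "LVI_IPCC"}
    if not needed <= set(df.columns):
        return []
    recomputed = (df["E"] - df["A"]) * df["S"]
    bad = df.index[(recomputed - df["LVI_IPCC"]).abs() > tol]
    if len(bad) == 0:
        return []
    return [
        "LVI_IPCC differs from (E - A) * S of the tabulated factors for: "
        + ", ".join(str(u) for u in bad)
    ]
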