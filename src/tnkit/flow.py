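"""Phospho-signaling fold-change normalization.

For a marker X measured by phospho-flow in monoculture and co-culture, the
co-culture effect on signaling is the ratio of phospho-to-total ratios:

    fold change = (pX_co / X_co) / (pX_mono / X_mono)

where pX and X are the percent-positive (or MFI) readouts of the
phosphorylated and total protein. A value above 1 means the co-culture
increased the phosphorylated fraction relative to total protein content.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

Condition = Literal["monoculture", "co-culture"]


@dataclass(frozen=True)
class FlowMeasurement:
    """One marker's phospho (pX) and total (X) readout in one condition."""

    marker: str
    population: str
    condition: str
    pX: float
    X: float

    def __post_init__(self) -> None:
        for name in ("pX", "X"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(
                    f"{self.marker}/{self.population}/{self.condition}: "
                    f"{name} must be finite and > 0, got {v}")


@dataclass(frozen=True)
class FoldChange:
    marker: str
    population: str
    value: float

    @property
    def log2(self) -> float:
        return math.log2(self.value)


def phospho_fold_change(
    m_co: FlowMeasurement,
    m_mono: FlowMeasurement,
) -> FoldChange:
    """Co-culture phospho/total ratio normalized to the monoculture ratio."""
    if m_co.marker != m_mono.marker or m_co.population != m_mono.population:
        raise ValueError(
            f"marker/population mismatch: {m_co.marker}/{m_co.population} "
            f"vs {m_mono.marker}/{m_mono.population}")
    value = (m_co.pX / m_co.X) / (m_mono.pX / m_mono.X)
    return FoldChange(marker=m_co.marker, population=m_co.population,
                      value=value)


def fold_change_table(df: pd.DataFrame, log2: bool = False) -> pd.DataFrame:
    """Fold changes for every (marker, population) in a long-format table.

    Input columns: marker, population, condition, pX, X with one
    monoculture and one co-culture row per (marker, population). Output
    columns: marker, population, fold_change (plus log2_fold_change when
    requested), heatmap-ready.
    """
    required = {"marker", "population", "condition", "pX", "X"}
    if not required <= set(df.columns):
        raise ValueError(f"flow table needs columns {required}")
    rows = []
    for (marker, pop), grp in df.groupby(["marker", "population"]):
        by_cond = {r.condition: FlowMeasurement(marker, pop, r.condition,
                                                float(r.pX), float(r.X))
                   for r in grp.itertuples()}
        missing = {"monoculture", "co-culture"} - set(by_cond)
        if missing:
            raise ValueError(f"{marker}/{pop}: missing condition(s) {missing}")
        fc = phospho_fold_change(by_cond["co-culture"], by_cond["monoculture"])
        row = {"marker": marker, "population": pop, "fold_change": fc.value}
        if log2:
            row["log2_fold_change"] = fc.log2
        rows.append(row)
    return pd.DataFrame(rows).sort_values(
        ["population", "marker"]).reset_index(drop=True)
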