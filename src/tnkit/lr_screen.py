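"""Ligand-receptor crosstalk screen by TPM expression thresholds.

A ligand-receptor (L-R) pair — either side possibly a multi-subunit
complex — passes a screen at threshold t when *every* subunit clears t TPM
in its assigned cell type: the ligand side in the ligand-expressing cell
and the receptor side in the receptor-expressing cell. The canonical
thresholds are an inclusive screen at >= 2 TPM and a conservative one at
>= 10 TPM, so the >= 10 pass set is always a subset of the >= 2 set.

Because the direction of signalling between activated CD8 T cells and NK
cells is not fixed a priori, the default mode ("either") accepts a pair if
it passes with the ligand on either cell type.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

T_CELL = "activated CD8 T"
NK_CELL = "NK"

Direction = Literal["ligand_on_a", "ligand_on_b", "either"]


@dataclass(frozen=True)
class LRPair:
    """A ligand-receptor gene pair; complexes hold several subunits."""

    ligand_subunits: tuple[str, ...]
    receptor_subunits: tuple[str, ...]
    role: str = ""

    def __post_init__(self) -> None:
        for side, subunits in (("ligand", self.ligand_subunits),
                               ("receptor", self.receptor_subunits)):
            if not subunits:
                raise ValueError(f"{side} side must have >= 1 subunit")
            if len(set(subunits)) != len(subunits):
                raise ValueError(f"duplicate subunit on {side} side")
            if any(s != s.upper() or not s for s in subunits):
                raise ValueError(
                    f"{side} subunits must be non-empty uppercase symbols")

    def key(self) -> str:
        return ("/".join(self.ligand_subunits) + "--"
                + "/".join(self.receptor_subunits))

    @property
    def genes(self) -> tuple[str, ...]:
        return self.ligand_subunits + self.receptor_subunits


@dataclass(frozen=True)
class ExpressionTable:
    """(gene, cell type) -> TPM lookup; missing genes are explicit misses."""

    values: Mapping[tuple[str, str], float]
    cell_types: tuple[str, ...]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionTable":
        """Build from long-format columns gene, cell_type, tpm."""
        required = {"gene", "cell_type", "tpm"}
        if not required <= set(df.columns):
            raise ValueError(f"expression table needs columns {required}")
        if (df["tpm"] < 0).any() or not df["tpm"].map(
                lambda v: v == v and abs(v) != float("inf")).all():
            raise ValueError("TPM values must be finite and >= 0")
        values = {(str(r.gene).upper(), str(r.cell_type)): float(r.tpm)
                  for r in df.itertuples()}
        cell_types = tuple(sorted(df["cell_type"].astype(str).unique()))
        return cls(values=values, cell_types=cell_types)

    def lookup(self, gene: str, cell_type: str) -> Optional[float]:
        """TPM of a gene in a cell type, or None when unmeasured."""
        if cell_type not in self.cell_types:
            raise ValueError(f"unknown cell type {cell_type!r}; "
                             f"table has {self.cell_types}")
        return self.values.get((gene.upper(), cell_type))


@dataclass(frozen=True)
class ScreenResult:
    threshold: float
    direction: str
    passing: tuple[LRPair, ...]
    failing: tuple[LRPair, ...]
    unevaluable: tuple[LRPair, ...]

    @property
    def n_passing(self) -> int:
        return len(self.passing)


def parse_pair_table(
    df: pd.DataFrame,
    separator: str = "/",
) -> list[LRPair]:
    """Parse a CellChat-style pair table into LRPair objects.

    Expects columns ``ligand`` and ``receptor`` (complex subunits joined by
    ``separator``) and optionally ``role``. Rows with an empty gene field
    are rejected with a logged reason; duplicate pairs are de-duplicated
    with a warning.
    """
    if not {"ligand", "receptor"} <= set(df.columns):
        raise ValueError("pair table needs 'ligand' and 'receptor' columns")
    pairs: list[LRPair] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        lig = str(row["ligand"]).strip() if pd.notna(row["ligand"]) else ""
        rec = str(row["receptor"]).strip() if pd.notna(row["receptor"]) else ""
        if not lig or not rec:
            logger.warning("row %s rejected: empty ligand or receptor field", i)
            continue
        pair = LRPair(
            ligand_subunits=tuple(s.strip().upper()
                                  for s in lig.split(separator)),
            receptor_subunits=tuple(s.strip().upper()
                                    for s in rec.split(separator)),
            role=str(row["role"]) if "role" in df.columns
            and pd.notna(row.get("role")) else "",
        )
        if pair.key() in seen:
            logger.warning("duplicate pair %s dropped", pair.key())
            continue
        seen.add(pair.key())
        pairs.append(pair)
    return pairs


def _side_passes(
    subunits: Sequence[str],
    expr: ExpressionTable,
    cell: str,
    threshold: float,
) -> Optional[bool]:
    """All-subunits rule on one side; None when any subunit is unmeasured."""
    verdict = True
    for g in subunits:
        tpm = expr.lookup(g, cell)
        if tpm is None:
            return None
        if tpm < threshold:
            verdict = False
    return verdict


def screen_pairs(
    pairs: Sequence[LRPair],
    expr: ExpressionTable,
    threshold: float,
    ligand_cell: str = T_CELL,
    receptor_cell: str = NK_CELL,
    direction: Direction = "either",
) -> ScreenResult:
    """Apply the inclusive all-subunits TPM threshold to every pair.

    A pair passes when every ligand subunit reaches ``threshold`` TPM in
    the ligand cell and every receptor subunit reaches it in the receptor
    cell. ``direction='either'`` (default) also accepts the swapped
    assignment. Pairs containing any unmeasured gene are reported as
    unevaluable, never counted as pass or fail.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if direction not in ("ligand_on_a", "ligand_on_b", "either"):
        raise ValueError(f"unknown direction {direction!r}")

    def verdict(pair: LRPair, lig_cell: str, rec_cell: str) -> Optional[bool]:
        vl = _side_passes(pair.ligand_subunits, expr, lig_cell, threshold)
        vr = _side_passes(pair.receptor_subunits, expr, rec_cell, threshold)
        return None if vl is None or vr is None else vl and vr

    passing, failing, unevaluable = [], [], []
    for pair in pairs:
        verdicts = []
        if direction in ("ligand_on_a", "either"):
            verdicts.append(verdict(pair, ligand_cell, receptor_cell))
        if direction in ("ligand_on_b", "either"):
            verdicts.append(verdict(pair, receptor_cell, ligand_cell))
        if any(v is True for v in verdicts):
            passing.append(pair)
        elif all(v is None for v in verdicts):
            unevaluable.append(pair)
            logger.warning("pair %s unevaluable: unmeasured gene", pair.key())
        else:
            failing.append(pair)
    return ScreenResult(threshold=threshold, direction=direction,
                        passing=tuple(passing), failing=tuple(failing),
                        unevaluable=tuple(unevaluable))


def count_by_threshold(flags: pd.DataFrame) -> dict[str, int]:
    """Count YES pairs per threshold column in a Table-1-style flag table.

    Expects boolean (or YES/blank) columns ``ge2`` and ``ge10``; validates
    the nesting invariant that a pair passing at >= 10 TPM also passes at
    >= 2 TPM.
    """
    def as_bool(col: pd.Series) -> pd.Series:
        if col.dtype == bool:
            return col
        return col.fillna("").astype(str).str.strip().str.upper() == "YES"

    ge2 = as_bool(flags["ge2"])
    ge10 = as_bool(flags["ge10"])
    bad = ge10 & ~ge2
    if bad.any():
        raise ValueError(
            f"inconsistent flags (YES at >=10 but not >=2) in rows "
            f"{list(flags.index[bad])}")
    return {"ge2": int(ge2.sum()), "ge10": int(ge10.sum())}


def load_reference_pairs() -> pd.DataFrame:
    """Packaged reference table of 16 curated T-NK crosstalk L-R pairs.

    Columns: ligand, receptor, role, ge2, ge10 — the pass flags at the two
    TPM thresholds.
    """
    with importlib.resources.files("tnkit.data").joinpath(
            "table1_pairs.csv").open() as fh:
        return pd.read_csv(fh)
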