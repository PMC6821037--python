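"""Per-block presence/absence grids for peak features across cell types.

A :class:`PresenceMatrix` records, for each LD block (row) and each
(cell type, feature) track (column), whether at least one peak of that track
falls inside the block. ``unavailable`` is a first-class cell state distinct
from ``N``: it marks tracks that simply do not exist for a cell type (e.g.
no public PBMC H3K27ac or neutrophil CTCF data), so absence of data is never
conflated with absence of signal.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = ["PresenceMatrix", "summarize_matrix", "UNAVAILABLE"]

UNAVAILABLE = "unavailable"
_VALID_CELLS = {"Y", "N", UNAVAILABLE}


class PresenceMatrix:
    """LD-block x (cell type, feature) grid of {Y, N, unavailable} cells."""

    def __init__(
        self,
        cells: pd.DataFrame,
        block_spans: Mapping[str, str] | None = None,
        significance: Mapping[str, bool | None] | None = None,
    ):
        bad = set(cells.values.ravel()) - _VALID_CELLS
        if bad:
            raise ValueError(f"invalid presence cells: {sorted(bad)}")
        if cells.isna().any().any():
            raise ValueError("presence matrix has unpopulated cells")
        self.cells = cells
        self.block_spans = dict(block_spans or {})
        # per-column flag: True/False once tested, None when not tested
        self.significance = {col: None for col in cells.columns}
        if significance:
            self.significance.update(significance)

    @property
    def columns(self) -> list[str]:
        return list(self.cells.columns)

    @property
    def rsids(self) -> list[str]:
        return list(self.cells.index)

    def column_counts(self) -> pd.Series:
        """Number of Y cells per column."""
        return (self.cells == "Y").sum()

    def conjunction_count(self, columns: Sequence[str]) -> int:
        """Rows where every one of the named columns is Y."""
        for col in columns:
            if col not in self.cells.columns:
                raise KeyError(f"presence matrix has no column {col!r}")
        return int((self.cells[list(columns)] == "Y").all(axis=1).sum())

    def to_tsv(self, path: str | Path) -> None:
        out = self.cells.copy()
        out.insert(0, "block", [self.block_spans.get(r, "") for r in out.index])
        out.to_csv(path, sep="\t", index_label="rsid")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PresenceMatrix":
        table = pd.read_csv(path, sep="\t", comment="#", index_col="rsid", dtype=str)
        spans = {}
        if "block" in table.columns:
            spans = table["block"].fillna("").to_dict()
            table = table.drop(columns=["block"])
        return cls(table, block_spans=spans)

    def plot(self, ax=None):
        """Heatmap of the grid (Y=1, N=0, unavailable hatched grey)."""
        import matplotlib.pyplot as plt
        import numpy as np

        if ax is None:
            _, ax = plt.subplots(
                figsize=(1 + 0.6 * len(self.columns), 1 + 0.3 * len(self.rsids))
            )
        numeric = self.cells.replace({"Y": 1.0, "N": 0.0, UNAVAILABLE: float("nan")})
        ax.imshow(numeric.to_numpy(dtype=float), cmap="Greys", vmin=0, vmax=1.4)
        ax.set_xticks(range(len(self.columns)), self.columns, rotation=90)
        ax.set_yticks(range(len(self.rsids)), self.rsids)
        return ax


def summarize_matrix(
    matrix: PresenceMatrix,
    conjunctions: Mapping[str, Sequence[str]] | None = None,
) -> dict:
    """Column Y-counts plus optional joint counts over column conjunctions.

    ``conjunctions`` maps a label to the columns that must all be Y, e.g.
    ``{"M0 CTCF & both marks": ["M0:CTCF", "M0:H3K4me1", "M0:H3K27ac"]}``.
    A conjunction naming a missing column raises ``KeyError``.
    """
    counts = matrix.column_counts()
    joint = {
        label: matrix.conjunction_count(cols)
        for label, cols in (conjunctions or {}).items()
    }
    return {"counts": counts, "conjunctions": joint}
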