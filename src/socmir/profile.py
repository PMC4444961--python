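"""Presence/absence profile matrix: assembly, filtering, ordering, I/O.

The central object of the analysis is a binary miRNA × genome matrix.
Figure-style presentation fixes the genome axis to the species phylogeny and
drops uninformative rows (present everywhere or in at most one genome).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PresenceAbsenceMatrix",
    "MatrixError",
    "filter_informative",
    "order_by_tree",
    "order_columns",
    "restrict_panel",
]


class MatrixError(ValueError):
    """Raised on inconsistent matrix construction or manipulation."""


class PresenceAbsenceMatrix:
    """Binary miRNA × genome presence/absence matrix.

    Backed by a pandas DataFrame of 0/1 int8 values (rows: miRNA names,
    columns: genome ids). ``cell_provenance`` optionally carries per-cell
    hit counts (same shape) or string provenance tags.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        cell_provenance: pd.DataFrame | None = None,
        panel_tag: str = "",
    ):
        if values.index.has_duplicates:
            raise MatrixError("duplicate row names")
        if values.columns.has_duplicates:
            raise MatrixError("duplicate column names")
        arr = values.to_numpy()
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise MatrixError("matrix values must be 0/1")
        self.values = values.astype("int8")
        if cell_provenance is not None:
            cell_provenance = cell_provenance.reindex(
                index=values.index, columns=values.columns
            )
        self.cell_provenance = cell_provenance
        self.panel_tag = panel_tag

    # -- accessors --------------------------------------------------------
    @property
    def row_names(self) -> list[str]:
        return list(self.values.index)

    @property
    def col_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def present_in(self, mirna: str) -> list[str]:
        row = self.values.loc[mirna]
        return [c for c in self.values.columns if row[c] == 1]

    def __getitem__(self, key: tuple[str, str]) -> int:
        mirna, genome = key
        return int(self.values.at[mirna, genome])

    def __eq__(self, other) -> bool:
        return isinstance(other, PresenceAbsenceMatrix) and self.values.equals(
            other.values
        )

    def _with(self, values: pd.DataFrame) -> "PresenceAbsenceMatrix":
        prov = None
        if self.cell_provenance is not None:
            prov = self.cell_provenance.reindex(
                index=values.index, columns=values.columns
            )
        return PresenceAbsenceMatrix(values, prov, self.panel_tag)

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="mirna")

    @classmethod
    def from_tsv(cls, path: str | Path, panel_tag: str = "") -> "PresenceAbsenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(df, panel_tag=panel_tag)

    @classmethod
    def from_dict(
        cls,
        presence: Mapping[str, Iterable[str]],
        columns: Sequence[str],
        panel_tag: str = "",
    ) -> "PresenceAbsenceMatrix":
        """Build from ``{mirna: iterable of genomes where present}``."""
        cols = list(columns)
        data = {}
        for name, present in presence.items():
            present = set(present)
            unknown = present - set(cols)
            if unknown:
                raise MatrixError(f"{name}: unknown genomes {sorted(unknown)}")
            data[name] = [1 if c in present else 0 for c in cols]
        df = pd.DataFrame.from_dict(data, orient="index", columns=cols)
        return cls(df, panel_tag=panel_tag)


def filter_informative(matrix: PresenceAbsenceMatrix) -> PresenceAbsenceMatrix:
    """Drop rows present in every genome or in at most one genome.

    The figure-style informativeness rule: a miRNA present everywhere or in
    only one species carries no grouping signal for the panel at hand. The
    filter is applied per panel; idempotent.
    """
    if matrix.shape[1] < 2:
        raise MatrixError("informativeness filter needs >= 2 columns")
    sums = matrix.values.sum(axis=1)
    keep = (sums > 1) & (sums < matrix.shape[1])
    return matrix._with(matrix.values.loc[keep])


def order_columns(
    matrix: PresenceAbsenceMatrix, column_order: Sequence[str]
) -> PresenceAbsenceMatrix:
    """Permute columns to the given order and sort rows by pattern.

    Rows are ordered lexicographically by their presence pattern read in the
    new column order (1 before 0, so clade-wide presences group at the top),
    ties broken by miRNA name.
    """
    if list(column_order) != matrix.col_names and set(column_order) != set(
        matrix.col_names
    ):
        raise MatrixError("column_order must be a permutation of the columns")
    df = matrix.values[list(column_order)]
    key = sorted(
        df.index, key=lambda r: (tuple(-int(v) for v in df.loc[r]), r)
    )
    return matrix._with(df.loc[key])


def order_by_tree(matrix: PresenceAbsenceMatrix, tree) -> PresenceAbsenceMatrix:
    """Permute columns to the tree's left-to-right leaf order and sort rows.

    Requires the matrix columns and tree leaves to coincide exactly. Stable:
    applying twice equals applying once.
    """
    leaf_order = tree.leaf_order()
    cols = set(matrix.col_names)
    leaves = set(leaf_order)
    if cols != leaves:
        raise MatrixError(
            f"tree/matrix mismatch: only in matrix {sorted(cols - leaves)}, "
            f"only in tree {sorted(leaves - cols)}"
        )
    return order_columns(matrix, leaf_order)


def restrict_panel(
    matrix: PresenceAbsenceMatrix, genome_ids: Sequence[str], panel_tag: str = ""
) -> PresenceAbsenceMatrix:
    """Column-subset the matrix to a genome panel; rows unchanged."""
    unknown = set(genome_ids) - set(matrix.col_names)
    if unknown:
        raise MatrixError(f"unknown genome ids: {sorted(unknown)}")
    out = matrix._with(matrix.values[list(genome_ids)])
    if panel_tag:
        out.panel_tag = panel_tag
    return out
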