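"""Map every cell to every cell set: the cell × cell-set membership matrix.

Each cell carries a provisional cell type assignment (its cluster from the
upstream classification).  A cell belongs to the leaf set of its type, to
every node/custom set whose label expression covers that leaf, and to every
metadata set whose predicate its metadata satisfies.  The result is a table
of binary calls (0 = excluded, 1 = included) with one row per cell and one
column per cell set, in accession-number order.  The format also admits
probabilistic values in [0, 1]; see :func:`aggregate_probabilities` for the
union contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import CCNError, CellSet, Taxonomy

__all__ = [
    "MappingError",
    "CellRecord",
    "MembershipMatrix",
    "read_cell_table",
    "map_cells",
    "aggregate_probabilities",
    "write_mapping",
    "read_mapping",
]


class MappingError(CCNError, ValueError):
    """Cells cannot be mapped to the taxonomy's cell sets."""


@dataclass(frozen=True)
class CellRecord:
    """One cell: unique id, provisional cell type, optional metadata."""

    cell_id: str
    provisional_type: str
    metadata: Mapping[str, str] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "metadata", dict(self.metadata or {}))


@dataclass(frozen=True)
class MembershipMatrix:
    """Cells × cell sets inclusion table; values in [0, 1], binary by default."""

    frame: pd.DataFrame  # index: cell_id; columns: accession strings

    def __post_init__(self) -> None:
        values = self.frame.to_numpy(dtype=float)
        if values.size and (np.isnan(values).any() or values.min() < 0 or values.max() > 1):
            raise MappingError("membership values must lie in [0, 1] with no gaps")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def accessions(self) -> list[str]:
        return list(self.frame.columns)

    def to_sparse(self):
        """The matrix as a scipy CSR sparse matrix (same row/column order)."""
        from scipy import sparse

        return sparse.csr_matrix(self.frame.to_numpy(dtype=float))


def read_cell_table(path: str | Path) -> list[CellRecord]:
    """Read a cell metadata CSV (``cell_id,provisional_type,<metadata...>``)."""
    frame = pd.read_csv(Path(path), dtype=str, keep_default_na=False, encoding="utf-8-sig")
    for col in ("cell_id", "provisional_type"):
        if col not in frame.columns:
            raise MappingError(f"cell table is missing required column {col!r}")
    meta_cols = [c for c in frame.columns if c not in ("cell_id", "provisional_type")]
    return [
        CellRecord(row["cell_id"], row["provisional_type"], {c: row[c] for c in meta_cols})
        for _, row in frame.iterrows()
    ]


def _leaf_resolver(tax: Taxonomy) -> dict[str, int]:
    """provisional_type text -> leaf numeral; matches the leaf's preferred
    alias (the publication cluster name) or its rendered cell set label."""
    resolver: dict[str, int] = {}
    for cs in tax.leaves():
        numeral = cs.label.numerals()[0]
        if cs.preferred_alias:
            resolver.setdefault(cs.preferred_alias, numeral)
        resolver.setdefault(cs.label.render(), numeral)
    return resolver


def map_cells(tax: Taxonomy, cells: Sequence[CellRecord], keep_unmapped: bool = False) -> MembershipMatrix:
    """Build the binary membership matrix for a taxonomy and its cells.

    Columns are ordered by accession number, one per cell set, none omitted.
    Cells whose provisional type resolves to no leaf are rejected (listed in
    the error) unless ``keep_unmapped`` is set, in which case they get
    all-zero rows.  Metadata-set predicates must name existing metadata
    columns.
    """
    ids = [c.cell_id for c in cells]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise MappingError(f"duplicate cell ids: {dupes[:10]}")
    resolver = _leaf_resolver(tax)
    unresolved = sorted({c.provisional_type for c in cells if c.provisional_type not in resolver})
    if unresolved and not keep_unmapped:
        raise MappingError(
            f"{len(unresolved)} provisional type(s) resolve to no leaf cell set: {unresolved[:10]}"
        )
    meta_columns = set()
    for c in cells:
        meta_columns.update(c.metadata)
    ordered = sorted(tax.cell_sets, key=lambda cs: cs.accession.number)
    matrix = np.zeros((len(cells), len(ordered)), dtype=np.int8)
    leaf_numeral = np.array(
        [resolver.get(c.provisional_type, 0) for c in cells], dtype=int
    )
    for j, cs in enumerate(ordered):
        if cs.kind == "metadata" and cs.predicate is not None:
            column, value = cs.predicate
            if column not in meta_columns:
                raise MappingError(
                    f"{cs.accession.render()}: predicate references unknown metadata column {column!r}"
                )
            matrix[:, j] = [1 if c.metadata.get(column) == value else 0 for c in cells]
        elif cs.kind == "metadata":
            # metadata set with no predicate on record: membership unknowable
            matrix[:, j] = 0
        else:
            members = np.isin(leaf_numeral, cs.label.numerals())
            matrix[:, j] = members.astype(np.int8)
    frame = pd.DataFrame(matrix, index=pd.Index(ids, name="cell_id"),
                         columns=[cs.accession.render() for cs in ordered])
    return MembershipMatrix(frame)


def aggregate_probabilities(tax: Taxonomy, leaf_probabilities: pd.DataFrame) -> MembershipMatrix:
    """Extend per-cell leaf probabilities to every cell set.

    ``leaf_probabilities`` has one row per cell and one column per leaf
    accession; each row must sum to at most 1 (leaves partition the cells).
    A union set's value is the sum of its member leaves' values, clipped to
    1; metadata sets (no leaf members) get 0.
    """
    sums = leaf_probabilities.sum(axis=1)
    if (sums > 1 + 1e-9).any():
        bad = list(leaf_probabilities.index[sums > 1 + 1e-9])[:5]
        raise MappingError(f"leaf probabilities must sum to <= 1 per cell; offending cells: {bad}")
    by_numeral = {cs.label.numerals()[0]: cs.accession.render() for cs in tax.leaves()}
    ordered = sorted(tax.cell_sets, key=lambda cs: cs.accession.number)
    out = {}
    for cs in ordered:
        if cs.kind == "metadata":
            out[cs.accession.render()] = np.zeros(len(leaf_probabilities))
            continue
        cols = [by_numeral[n] for n in cs.label.numerals() if n in by_numeral]
        cols = [c for c in cols if c in leaf_probabilities.columns]
        total = leaf_probabilities[cols].sum(axis=1) if cols else pd.Series(0.0, index=leaf_probabilities.index)
        out[cs.accession.render()] = np.clip(total.to_numpy(), 0.0, 1.0)
    frame = pd.DataFrame(out, index=leaf_probabilities.index)
    frame.index.name = "cell_id"
    return MembershipMatrix(frame)


def write_mapping(matrix: MembershipMatrix, path: str | Path) -> Path:
    """Write the membership matrix CSV: ``cell_id`` column then accessions."""
    path = Path(path)
    frame = matrix.frame
    if (frame.to_numpy() == frame.to_numpy().astype(np.int64)).all():
        frame = frame.astype(np.int64)
    frame.to_csv(path, encoding="utf-8")
    return path


def read_mapping(path: str | Path) -> MembershipMatrix:
    """Read a membership CSV back; ragged rows or out-of-range values fail."""
    frame = pd.read_csv(Path(path), index_col="cell_id", encoding="utf-8-sig")
    if frame.isna().to_numpy().any():
        raise MappingError(f"{path}: ragged or missing values in membership table")
    return MembershipMatrix(frame)
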