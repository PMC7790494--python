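"""Synthetic taxonomies and bundled worked-example records.

``simulate_taxonomy`` generates the three inputs the CCN expects — a random
hierarchical dendrogram, per-leaf publication-style cluster names, and a
cell metadata table with provisional type assignments plus a tissue column —
fully determined by an integer seed.  Only taxonomy *structure* and metadata
are modeled; no gene expression is simulated.

``reference_bundle`` exposes transcriptions of published CCN records that
ship with the package: the eight Sst Chodl cell sets spanning the primary
motor cortex taxonomies (all with structure "primary motor cortex",
UBERON:0001384), the 18-taxonomy registry manifest, and the human MTG
taxonomy defaults.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .dendrogram import DendNode, write_dendrogram
from .mapping import CellRecord
from .model import TaxonomyDefaults, ValidationError, make_taxonomy_id

__all__ = [
    "simulate_taxonomy",
    "write_simulation",
    "cells_to_frame",
    "data_path",
    "reference_bundle",
    "ReferenceBundle",
    "MTG_DEFAULTS",
]

#: Taxonomy-wide defaults used when the CCN was applied to human middle
#: temporal gyrus: taxonomy id, curator, data citation, anatomical structure
#: with its UBERON tag, and the cell set label prefix.
MTG_DEFAULTS = TaxonomyDefaults(
    taxonomy_id=make_taxonomy_id("2019-08-21", 0),
    assignee="Trygve Bakken",
    citation="10.1038/s41586-019-1506-7",
    structure="middle temporal gyrus",
    ontology_tag="UBERON:0002771",
    prefix="MTG",
    pad_width=3,
)


def _draw_count(rng: np.random.Generator, spec) -> int:
    if isinstance(spec, int):
        return spec
    kind, param = spec
    if kind == "const":
        return int(param)
    if kind == "poisson":
        if param <= 0:
            raise ValidationError(f"poisson rate must be positive, got {param}")
        return int(rng.poisson(param))
    raise ValidationError(f"unknown cells-per-leaf distribution {spec!r}")


def simulate_taxonomy(
    n_leaves: int,
    branching: int = 2,
    cells_per_leaf=("poisson", 200),
    seed: int = 0,
    label_stem: str = "Type",
    neurosurgical_fraction: float = 0.1,
) -> tuple[DendNode, list[CellRecord]]:
    """Generate a random dendrogram and matching cell metadata.

    The tree is built by recursive random splits of the ordered leaf
    sequence; with ``branching=2`` every internal node is binary, larger
    values allow nodes with up to ``branching`` children.  Leaves are named
    ``"<label_stem> 001"`` … in tree order.  Each leaf receives a number of
    cells drawn from ``cells_per_leaf`` (an int, ``("const", k)`` or
    ``("poisson", rate)``); every cell carries a ``tissue`` metadata column
    (``neurosurgical`` with the given probability, else ``postmortem``).
    Identical seeds reproduce identical outputs byte for byte.
    """
    if n_leaves < 1:
        raise ValidationError(f"n_leaves must be >= 1, got {n_leaves}")
    if branching < 2:
        raise ValidationError(f"branching must be >= 2, got {branching}")
    rng = np.random.default_rng(seed)
    counter = {"node": 0}

    def split(lo: int, hi: int) -> DendNode:
        # leaves are positions lo..hi (1-based, inclusive)
        if lo == hi:
            return DendNode(node_id=f"leaf{lo}", original_label=f"{label_stem} {lo:03d}")
        counter["node"] += 1
        node = DendNode(node_id=f"node{counter['node']}")
        width = hi - lo + 1
        k = int(rng.integers(2, min(branching, width) + 1))
        cuts = sorted(rng.choice(np.arange(lo, hi), size=k - 1, replace=False).tolist())
        bounds = [lo - 1] + cuts + [hi]
        for a, b in zip(bounds[:-1], bounds[1:]):
            node.children.append(split(a + 1, b))
        return node

    root = split(1, n_leaves)
    cells: list[CellRecord] = []
    cell_no = 0
    for i in range(1, n_leaves + 1):
        count = _draw_count(rng, cells_per_leaf)
        for _ in range(count):
            cell_no += 1
            tissue = "neurosurgical" if rng.random() < neurosurgical_fraction else "postmortem"
            cells.append(CellRecord(
                cell_id=f"cell_{cell_no:06d}",
                provisional_type=f"{label_stem} {i:03d}",
                metadata={"tissue": tissue},
            ))
    return root, cells


def cells_to_frame(cells: list[CellRecord]) -> pd.DataFrame:
    """Cell records as a ``cell_id,provisional_type,<metadata...>`` frame."""
    meta_cols = sorted({k for c in cells for k in c.metadata})
    rows = [
        {"cell_id": c.cell_id, "provisional_type": c.provisional_type,
         **{k: c.metadata.get(k, "") for k in meta_cols}}
        for c in cells
    ]
    return pd.DataFrame(rows, columns=["cell_id", "provisional_type", *meta_cols])


def write_simulation(root: DendNode, cells: list[CellRecord], out_dir: str | Path) -> tuple[Path, Path]:
    """Write a simulated fixture to ``dendrogram.json`` and ``cells.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dend_path = out_dir / "dendrogram.json"
    write_dendrogram(root, dend_path)
    cells_path = out_dir / "cells.csv"
    cells_to_frame(cells).to_csv(cells_path, index=False, encoding="utf-8")
    return dend_path, cells_path


def data_path(name: str) -> Path:
    with resources.as_file(resources.files("ccnkit").joinpath(f"data/{name}")) as p:
        return p


@dataclass(frozen=True)
class ReferenceBundle:
    """Bundled transcriptions of published CCN records."""

    sst_chodl: pd.DataFrame      # 8 Sst Chodl cell sets, nomenclature-table columns
    registry_manifest: pd.DataFrame  # taxonomy_id, description, citation, file
    mtg_defaults: TaxonomyDefaults


def reference_bundle() -> ReferenceBundle:
    """Load the bundled worked-example records."""
    sst = pd.read_csv(data_path("sst_chodl_cell_sets.csv"), dtype=str, keep_default_na=False)
    manifest = pd.read_csv(data_path("taxonomy_registry.csv"), dtype=str, keep_default_na=False)
    return ReferenceBundle(sst_chodl=sst, registry_manifest=manifest, mtg_defaults=MTG_DEFAULTS)
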