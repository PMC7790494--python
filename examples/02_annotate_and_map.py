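"""The curation round trip and the cell x cell-set membership matrix.

Builds a taxonomy, adds a metadata-defined cell set (cells from
neurosurgical tissue), applies a curator's edits table (a literature alias
plus an aligned alias), then maps every cell to every cell set.
"""

import pandas as pd

from ccnkit import add_cell_set, apply_annotations, build_taxonomy, map_cells
from ccnkit.fixtures import simulate_taxonomy
from ccnkit.model import TaxonomyDefaults, parse_taxonomy_id

root, cells = simulate_taxonomy(6, cells_per_leaf=("const", 10), seed=2)
defaults = TaxonomyDefaults(parse_taxonomy_id("CCN202001010"), prefix="MTG",
                            structure="neocortex", ontology_tag="UBERON:0001950")
tax = build_taxonomy(defaults, root)

# a cell set defined by metadata, not by cell type
tax = add_cell_set(tax, kind="metadata", preferred_alias="Neurosurgical",
                   predicate=("tissue", "neurosurgical"))

# a curator's edits: blank = leave unchanged, '-' = clear
edits = pd.DataFrame([{
    "cell_set_accession_id": "CS202001010_1",
    "cell_set_aligned_alias": "Lamp5 1",
    "cell_set_additional_aliases": "Rosehip",
    "cell_set_alias_assignee": "A. Curator",
}])
tax = apply_annotations(tax, edits)
cs1 = tax.get("CS202001010_1")
print(f"{cs1.accession.render()}: aligned={cs1.aligned_alias!r}, "
      f"additional={list(cs1.additional_aliases)}")

matrix = map_cells(tax, cells).frame
print(f"membership matrix: {matrix.shape[0]} cells x {matrix.shape[1]} cell sets")
root_col = next(c.accession.render() for c in tax.cell_sets if c.label.render() == "MTG 001-006")
meta_col = tax.cell_sets[-1].accession.render()
print(f"cells in the root set {root_col}: {matrix[root_col].sum()} (all 60 cells)")
print(f"cells in metadata set {meta_col} (neurosurgical tissue): {matrix[meta_col].sum()}")
# Every cell is in exactly one leaf set, in each ancestor node set, and in
# any metadata set whose predicate its metadata satisfies.
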