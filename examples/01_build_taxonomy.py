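"""Apply the CCN to a small taxonomy: mint accessions and labels.

Simulates a 6-type hierarchical taxonomy, applies the nomenclature with
MTG-style defaults, and prints the resulting cell sets.  Leaves are numbered
1..6 in tree order and keep their cluster names as preferred aliases;
internal nodes get range labels like "MTG 001-006" describing exactly which
provisional types they contain.
"""

from ccnkit import build_taxonomy, validate_taxonomy
from ccnkit.fixtures import simulate_taxonomy
from ccnkit.model import TaxonomyDefaults, parse_taxonomy_id

root, cells = simulate_taxonomy(6, cells_per_leaf=("const", 10), seed=2)
defaults = TaxonomyDefaults(
    taxonomy_id=parse_taxonomy_id("CCN202001010"),
    assignee="A. Curator",
    citation="10.1000/example",
    structure="neocortex",
    ontology_tag="UBERON:0001950",
    prefix="MTG",
)
tax = build_taxonomy(defaults, root)

print(f"taxonomy {tax.id.render()}: {len(tax)} cell sets "
      f"({len(tax.leaves())} leaves), violations: {validate_taxonomy(tax)}")
for cs in tax.cell_sets:
    print(f"  {cs.accession.render():>18}  {cs.label.render():<14} "
          f"{cs.kind:<5} {cs.preferred_alias}")
# Each line is one cell set: its permanent accession, its range-notation
# label (which numerals = which provisional types it contains), its kind,
# and the publication-facing name (blank for unnamed internal nodes).
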