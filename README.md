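# ccnkit

Tools for the **Common Cell Type Nomenclature (CCN)** — a convention for
tagging, tracking, and cross-linking data-driven cell type classifications
(taxonomies) from single-cell and bulk experiments, modelled on how gene
transcripts are tracked across genome builds.

Single-cell RNA-seq and related modalities produce taxonomies of
quantitatively derived clusters ("provisional cell types") whose ad hoc
names make cross-study comparison hard. The CCN addresses this by giving

* every **taxonomy** a unique id `CCN[YYYYMMDD][#]` (date + same-day index);
* every **cell set** — a provisional type, a group of types, or a
  metadata-defined group — a permanent accession `CS[YYYYMMDD][#]_[n]`
  whose date/index segment matches its taxonomy;
* every cell set a **label** in range notation over the leaf numerals it
  contains (`MTG 001-006`, `RNA-seq 040, 046-047, 050-052, 068`), so
  composite sets are self-describing;
* up to three kinds of **aliases**: one *preferred* alias (the publication
  name), one *aligned* alias drawn from a controlled cortical vocabulary
  (`L2/3 IT 4`, `Pvalb 3`, `Microglia 2`, `Chandelier 1`) that links matched
  cell sets across taxonomies the way a gene symbol links orthologs, and
  free *additional* aliases — including cross-taxonomy references of the
  form `"RNA-seq 040 in CCN201912131"`;
* anatomy tags (`structure` + UBERON CURIE) and per-alias provenance
  (assignee, citation).

ccnkit implements the full workflow: derive cell sets from a taxonomy
dendrogram, mint identifiers, write/read the nomenclature table CSV, apply
curated annotation edits, map every cell to every cell set (the binary
cell × cell-set membership matrix), validate aligned aliases against the
cortical naming grammar, and link cell sets across any number of
taxonomies via an alias/reference graph. It is intended for groups applying
the CCN to their own clustering results and for anyone integrating
published taxonomies.

## Worked example

```python
from ccnkit import build_taxonomy, validate_taxonomy
from ccnkit.fixtures import simulate_taxonomy
from ccnkit.model import TaxonomyDefaults, parse_taxonomy_id

root, cells = simulate_taxonomy(6, cells_per_leaf=("const", 10), seed=2)
defaults = TaxonomyDefaults(
    taxonomy_id=parse_taxonomy_id("CCN202001010"),
    assignee="A. Curator", citation="10.1000/example",
    structure="neocortex", ontology_tag="UBERON:0001950", prefix="MTG",
)
tax = build_taxonomy(defaults, root)
```

Printing the cell sets (`examples/01_build_taxonomy.py`) gives:

```
taxonomy CCN202001010: 11 cell sets (6 leaves), violations: []
       CS202001010_1  MTG 001        leaf  Type 001
       ...
       CS202001010_6  MTG 006        leaf  Type 006
       CS202001010_7  MTG 001-006    node
       CS202001010_8  MTG 001-005    node
       ...
```

The six provisional types become leaf cell sets numbered 1–6 in tree order,
each keeping its cluster name as preferred alias; internal nodes follow at
7.. with range labels stating exactly which types they contain, and an empty
report from `validate_taxonomy` confirms all identifier invariants hold.

Cross-taxonomy linking (`examples/03_crosslink.py`) loads the bundled
records for the Sst Chodl interneuron — the rare long-range-projecting
cortical GABAergic type — across eight motor-cortex taxonomies spanning
transcriptomics, ATAC-seq and DNA methylation in human, marmoset and mouse,
and prints:

```
8 taxonomies loaded; component of CS201912131_40 has 8 cell sets
```

Seven of the eight records share the aligned alias `Sst Chodl`; the eighth
(a DNA-methylation cluster that merged several Sst types) is pulled into
the same component by its label reference
`"RNA-seq 040, 046-047, 050-052, 068 in CCN201912131"`, which resolves to
the transcriptomic Sst Chodl leaf.

The same operations are available from the shell:

```sh
ccn simulate --n-leaves 6 --seed 1 --out-dir sim/
ccn build --dendrogram sim/dendrogram.json --taxonomy-id CCN202001010 \
    --prefix MTG --structure neocortex --ontology-tag UBERON:0001950 --out-dir out/
ccn annotate --table out/nomenclature.csv --edits edits.csv --out annotated.csv
ccn map --table annotated.csv --cells sim/cells.csv --out mapping.csv
ccn validate --table annotated.csv
ccn crosslink --records records.csv --out components.csv
```

Exit codes: 0 ok, 1 validation failure, 2 usage error.

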