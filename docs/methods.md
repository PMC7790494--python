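# Methods

## The nomenclature model

A *taxonomy* is the output of one classification algorithm on one dataset.
ccnkit models it as an immutable `Taxonomy` value holding a `TaxonomyId`
(`CCN` + zero-padded `YYYYMMDD` + a non-negative same-day index, rendered
without padding), a tuple of `CellSet`s, and the taxonomy-wide defaults that
seeded them. Each `CellSet` carries:

* a `CellSetAccession` — `CS<taxonomy digits>_<n>`, `n` 1-based, unique
  within the taxonomy, globally unique across a registry, and permanent
  (numbers are never reused after deletion; new sets always take
  max + 1);
* a `LabelExpression` — a prefix plus an ordered tuple of disjoint inclusive
  integer ranges over leaf numerals. Compaction collapses maximal runs of
  consecutive integers, so the rendered label is minimal (the number of
  terms equals the number of runs); expansion enumerates the members. These
  two operations are exact inverses, which the tests check against
  brute-force enumeration and an independent run-length count;
* aliases with roles `preferred` (≤ 1), `aligned` (≤ 1) and `additional`
  (any number), each with optional assignee/citation provenance, plus
  cell-set-level assignee/citation columns for the CSV;
* anatomy (`structure` text + ontology CURIE) and a `kind`
  (`leaf` / `node` / `custom` / `metadata`).

`validate_taxonomy` returns violations as sorted data
(`DUPLICATE_ACCESSION`, `DUPLICATE_LABEL`, `MULTIPLE_PREFERRED_ALIAS`,
`MULTIPLE_ALIGNED_ALIAS`, `ACCESSION_TAXONOMY_MISMATCH`,
`LEAF_NUMERAL_GAP`, `LEAF_MULTIPLE_NUMERALS`) rather than raising, so a
curation pipeline can report everything at once; sorting makes the check
idempotent and independent of cell set order. Uniqueness is checked locally
(within a taxonomy, and across whatever is loaded into a `Registry`); a
global cross-institution id registry is a service problem, out of scope.

### Dialect choices

Publications print range labels with an en dash ("001–006") and pad
numerals inconsistently ("MTG 001" alongside "DNAm 12" and "ATAC-seq 08").
Machine output here always uses the ASCII hyphen-minus (CSV portability);
parsers accept hyphen, en dash and em dash, and are padding-agnostic,
inferring the pad width as the widest numeral seen. Pad width is per-prefix
configuration with default 3. The same-day index of a taxonomy id defaults
to a single digit starting at 0 but the grammar permits multi-digit
indices.

## Dendrograms and cell set derivation

Taxonomy trees are plain JSON (schema in
`src/ccnkit/data/dendrogram.schema.json`; canonical serialization uses
sorted keys and explicit `children` arrays, so serialization is
deterministic and round trips byte-for-byte). Trees need not be binary;
any internal node with ≥ 2 children is legal, and non-hierarchical
("community structure") taxonomies bypass the tree entirely by declaring
cell sets through label expressions. Schema validation is implemented as
explicit structural checks with positioned error messages.

`build_taxonomy` numbers leaves 1..L in left-to-right depth-first order —
the leaf accession number equals the leaf position, and the leaf's label
numeral is that position — then numbers internal nodes L+1.. in depth-first
pre-order. The pre-order choice is a design decision: nothing in the
convention fixes the internal-node order, and pre-order is deterministic,
cheap, and keeps leaves in the low numerals. Leaves keep their publication
cluster name as preferred alias; internal nodes start unnamed. A node's
label is the compaction of its leaf span, which equals the union of its
children's spans (sibling spans are disjoint — a property test).

`annotate_dendrogram` matches nodes to cell sets by leaf span and attaches
accession, label and both alias fields to every node; it fails listing all
orphan nodes, and is idempotent.

## The annotation round trip

Curation is spreadsheet-mediated: the nomenclature table CSV (fixed
12-column header, UTF-8, `|`-delimited additional aliases, BOM tolerated on
read) goes out, and an edits table with the same header comes back. Edits
are full-row upserts keyed by accession with explicit clear semantics —
blank means "leave unchanged", the literal `-` means "clear" — because a
spreadsheet cannot otherwise distinguish "no opinion" from "remove".
Assignee/citation on an edit row become provenance on each alias the row
changes. Aligned aliases are checked against the naming grammar: warning by
default, error under `strict_aligned` (the controlled vocabulary only
binds when a reference comparison actually exists). Membership predicates
of metadata/custom sets have no column in the fixed header, so they
serialize to a `<table>.members.json` sidecar written only when present;
this keeps the header exact and the round trip lossless.

## Cell-to-cell-set mapping

Cells (unique id, provisional type, optional metadata columns) map to cell
sets by three rules: a cell is in the leaf set its provisional type
resolves to (matching either the leaf's preferred alias or its rendered
label); in every node/custom set whose label numerals include that leaf;
and in every metadata set whose predicate (`column == value`) its metadata
satisfies. The result is a binary matrix, columns in accession-number
order, none omitted. Row invariants (exactly one leaf membership per cell;
node column = max over member leaf columns) are property-tested on seeded
fixtures. Unresolvable cells are rejected with a list, or given all-zero
rows under `keep_unmapped`. The format admits probabilistic values in
[0, 1]; `aggregate_probabilities` implements the value contract — per-cell
leaf probabilities must sum to ≤ 1 (leaves partition cells), and a union
set's value is the clipped sum of its member leaves — while estimating
such probabilities is out of scope.

## The cortical naming grammar

Aligned aliases follow a four-class grammar: glutamatergic
`[Layer] [Projection] #` (layer and projection both mandatory), GABAergic
`[Canonical gene(s)] #`, non-neuronal `[Cell class] #`, historical
`[Historical name] #`; the trailing ordinal is optional. Class is decided
by the leading token against the vocabulary, which ships as an editable
JSON file (the convention is explicitly a starting point, so nothing is
hard-coded): layer tokens including compounds (`L2/3`, `L5/6`), projection
tokens `IT/ET/CT/NP` with an alias map (`CF`, the corticofugal synonym,
canonicalizes to `ET`), gene symbols matched case-insensitively but
canonicalized to the config's casing (`PVALB 3` → genes `("Pvalb",)`), and
class/historical terms matched case-insensitively as whole phrases. An
underscore before the ordinal (`L6 CT_1`) is normalized to a space; the
canonical rendering always re-parses to the same term. Failures name the
first offending token. The grammar is deliberately permissive about the
number of GABAergic genes and about multi-word historical names, since the
convention does not restrict either.

## Cross-taxonomy linking

`build_link_graph` creates one node per (taxonomy, cell set) over a
registry and three edge kinds:

* **alias** edges between cell sets in *different* taxonomies whose aligned
  aliases are identical non-empty strings after whitespace normalization.
  No fuzzy matching — conflating `L6 CT_1` and `L6 CT 1` silently would be
  worse than missing the link; callers wanting that use the naming module's
  canonicalizer first. Restricted to alias edges, connected components are
  exactly the equivalence classes of aligned-alias strings (tested against
  a brute-force union-find closure).
* **reference** edges from a cell set to each cell set its
  `"<labels> in <taxonomy id>"` additional aliases resolve to. References
  resolve to the sets whose labels cover exactly the referenced numerals —
  a reference to part of a node's span links the leaves, not the node.
  References to taxonomies or labels not in the registry are logged and
  skipped, never materialized as dangling nodes, so partial registries
  (e.g. the bundled eight-record excerpt) stay interpretable. Whether such
  an edge means "matched" or merely "overlapping" is left to the reader;
  the graph records it either way.
* **co_cell** edges (opt-in) between cell sets of different taxonomies over
  the same dataset whose member cell-id sets are identical.

`transfer_aligned_aliases` copies aligned aliases from a reference taxonomy
along an externally supplied accession correspondence (the upstream
computational alignment is not part of the CCN), recording the source
taxonomy id as alias citation; it is idempotent. Merging taxonomies and
deciding what counts as "the reference" are out of scope.

## Synthetic data

`fixtures.simulate_taxonomy` generates the structure the CCN consumes and
nothing more: a random tree built by recursive random splits of the ordered
leaf sequence (binary by default; a `branching` parameter exercises
non-binary nodes), publication-style leaf names, and a cell table with a
`tissue` metadata column (`neurosurgical` with probability 0.1, else
`postmortem` — a realistic minority fraction for human cortical surgical
tissue, and enough to exercise metadata sets). Defaults of 75 leaves and
~200 cells per leaf (Poisson) match the scale of a published human cortical
taxonomy; tests use 6–23 leaves and constant 5–10 cells per leaf to keep
the suite fast. Everything is driven by `numpy.random.default_rng(seed)`,
so identical seeds give byte-identical files. The generator does **not**
simulate gene expression, cluster uncertainty, doublets, or imbalanced
cluster separability — passing tests demonstrate the bookkeeping
(identifiers, derivation, mapping, linking) is correct, not that any
clustering upstream of the CCN is.

Bundled with the package are transcriptions of published CCN records used
as worked examples: the eight Sst Chodl cell sets across motor-cortex
taxonomies (`data/sst_chodl_cell_sets.csv`), the 18-taxonomy registry
manifest (`data/taxonomy_registry.csv`; its `citation`/`file` columns are
intentionally empty — only ids and descriptions are public fixtures, and
the registry supports metadata-only stub entries for exactly this case),
and the human MTG defaults tuple (`fixtures.MTG_DEFAULTS`).

## Numerical and degenerate-input choices

* Probabilistic row-sum check uses a 1e-9 tolerance; all other comparisons
  are exact integer/string operations.
* A single-leaf tree builds one cell set (accession 1); an empty numeral
  set cannot be compacted (error); a zero-cell mapping is a valid empty
  matrix.
* Label collisions on `add_cell_set` are errors even when membership
  duplicates an existing set — duplicate *membership* with a distinct label
  and accession is allowed, duplicate *labels* never.
* Component reports number components deterministically by their smallest
  accession; all CLI outputs are byte-stable across reruns (sorted JSON
  keys, no timestamps).

## Known limitations

* Uniqueness is enforced per process/registry, not globally across
  institutions.
* The bundled vocabulary is a minimal cortical starter set; real
  deployments should extend the JSON config.
* The dendrogram JSON dialect is this package's canonical schema;
  converters for other tree dialects are left to users.
* `read_nomenclature_table` reconstructs taxonomy defaults from modal
  column values, which is exact for tables this package wrote but
  approximate for hand-assembled tables.
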