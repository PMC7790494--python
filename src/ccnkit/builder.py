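"""Apply the CCN to a taxonomy: mint accessions and labels, read/write tables.

``build_taxonomy`` turns a dendrogram plus taxonomy-wide defaults into a
:class:`~ccnkit.model.Taxonomy`: leaves become cell sets numbered 1..L in
left-to-right tree order (each keeping its publication name as preferred
alias), internal nodes follow at L+1.. in depth-first pre-order with blank
preferred aliases, and every set inherits the default assignee, citation,
structure and ontology tag.  ``add_cell_set`` appends custom unions and
metadata-defined sets with the next free accession number (max + 1;
accessions are permanent and never reused).  The nomenclature table is the
spreadsheet-facing CSV exchanged with curators.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .dendrogram import DendNode, leaf_order, node_leaf_spans
from .model import (
    Alias,
    CCNError,
    CellSet,
    LabelExpression,
    Taxonomy,
    TaxonomyDefaults,
    compact_labels,
    make_accession,
    parse_accession,
    parse_label_expression,
)

__all__ = [
    "BuildError",
    "NOMENCLATURE_COLUMNS",
    "build_taxonomy",
    "add_cell_set",
    "write_nomenclature_table",
    "read_nomenclature_table",
]

#: Fixed column order of the nomenclature table CSV.
NOMENCLATURE_COLUMNS = (
    "taxonomy_id",
    "cell_set_accession_id",
    "cell_set_label",
    "cell_set_preferred_alias",
    "cell_set_aligned_alias",
    "cell_set_additional_aliases",
    "cell_set_alias_assignee",
    "cell_set_alias_citation",
    "cell_set_structure",
    "cell_set_ontology_tag",
    "cell_set_level",
    "cell_set_kind",
)


class BuildError(CCNError, ValueError):
    """Inputs cannot be assembled into a valid taxonomy."""


def build_taxonomy(defaults: TaxonomyDefaults, root: DendNode, description: str = "") -> Taxonomy:
    """Mint cell sets for every leaf and internal node of a dendrogram."""
    leaves = leaf_order(root)
    labels = [leaf.original_label for leaf in leaves]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise BuildError(f"duplicate leaf labels in dendrogram: {sorted(dupes)}")
    spans = node_leaf_spans(root)
    cell_sets: list[CellSet] = []
    for i, leaf in enumerate(leaves, start=1):
        aliases = []
        if leaf.original_label:
            aliases.append(Alias(leaf.original_label, "preferred"))
        cell_sets.append(CellSet(
            accession=make_accession(defaults.taxonomy_id, i),
            label=LabelExpression(defaults.prefix, ((i, i),), defaults.pad_width),
            aliases=tuple(aliases),
            alias_assignee=defaults.assignee,
            alias_citation=defaults.citation,
            structure=defaults.structure,
            ontology_tag=defaults.ontology_tag,
            kind="leaf",
        ))
    n = len(leaves)
    for node in root.walk():
        if node.is_leaf:
            continue
        n += 1
        cell_sets.append(CellSet(
            accession=make_accession(defaults.taxonomy_id, n),
            label=compact_labels(defaults.prefix, spans[node.node_id], defaults.pad_width),
            aliases=(),
            alias_assignee=defaults.assignee,
            alias_citation=defaults.citation,
            structure=defaults.structure,
            ontology_tag=defaults.ontology_tag,
            kind="node",
        ))
    return Taxonomy(defaults.taxonomy_id, tuple(cell_sets), defaults, description)


def add_cell_set(
    tax: Taxonomy,
    members: LabelExpression | str | Iterable[int] | None = None,
    kind: str = "custom",
    preferred_alias: str = "",
    aligned_alias: str = "",
    additional_aliases: Sequence[str] = (),
    predicate: tuple[str, str] | None = None,
    level: str = "",
) -> Taxonomy:
    """Append one custom or metadata cell set, numbered max accession + 1.

    ``members`` gives the union of provisional-type numerals (a label
    expression, its rendered text, or a bare numeral iterable using the
    taxonomy's default prefix).  Metadata sets instead carry a membership
    ``predicate`` ``(metadata column, value)`` and are labelled with the
    metadata prefix and a running numeral ("Metadata 1", "Metadata 2", …).
    """
    if kind not in ("custom", "metadata"):
        raise BuildError(f"add_cell_set kind must be 'custom' or 'metadata', got {kind!r}")
    defaults = tax.defaults or TaxonomyDefaults(tax.id)
    if kind == "metadata":
        if predicate is None and members is None:
            raise BuildError("metadata cell set needs a membership predicate")
        k = sum(1 for cs in tax.cell_sets if cs.kind == "metadata") + 1
        label = LabelExpression(defaults.metadata_prefix, ((k, k),), 1)
    else:
        if members is None:
            raise BuildError("custom cell set needs member numerals or a label expression")
        if isinstance(members, LabelExpression):
            label = members
        elif isinstance(members, str):
            label = parse_label_expression(members)
        else:
            label = compact_labels(defaults.prefix, members, defaults.pad_width)
        leaf_numerals = {n for cs in tax.leaves() for n in cs.label.numerals()}
        unknown = set(label.numerals()) - leaf_numerals
        if unknown and label.prefix == defaults.prefix:
            raise BuildError(f"custom cell set references unknown leaf numerals: {sorted(unknown)}")
    existing = {cs.label.render() for cs in tax.cell_sets}
    if label.render() in existing:
        raise BuildError(f"label collision: {label.render()!r} already exists in {tax.id.render()}")
    aliases = []
    if preferred_alias:
        aliases.append(Alias(preferred_alias, "preferred"))
    if aligned_alias:
        aliases.append(Alias(aligned_alias, "aligned"))
    aliases.extend(Alias(t, "additional") for t in additional_aliases if t)
    new_set = CellSet(
        accession=make_accession(tax.id, tax.max_number() + 1),
        label=label,
        aliases=tuple(aliases),
        alias_assignee=defaults.assignee,
        alias_citation=defaults.citation,
        structure=defaults.structure,
        ontology_tag=defaults.ontology_tag,
        kind=kind,
        level=level,
        predicate=predicate,
    )
    return tax.with_cell_sets(tax.cell_sets + (new_set,))


# ---------------------------------------------------------------------------
# nomenclature table CSV
# ---------------------------------------------------------------------------

def taxonomy_to_frame(tax: Taxonomy) -> pd.DataFrame:
    """The nomenclature table as a DataFrame in the fixed column order."""
    rows = []
    for cs in tax.cell_sets:
        rows.append({
            "taxonomy_id": tax.id.render(),
            "cell_set_accession_id": cs.accession.render(),
            "cell_set_label": cs.label.render(),
            "cell_set_preferred_alias": cs.preferred_alias,
            "cell_set_aligned_alias": cs.aligned_alias,
            "cell_set_additional_aliases": "|".join(cs.additional_aliases),
            "cell_set_alias_assignee": cs.alias_assignee,
            "cell_set_alias_citation": cs.alias_citation,
            "cell_set_structure": cs.structure,
            "cell_set_ontology_tag": cs.ontology_tag,
            "cell_set_level": cs.level,
            "cell_set_kind": cs.kind,
        })
    return pd.DataFrame(rows, columns=list(NOMENCLATURE_COLUMNS))


def write_nomenclature_table(tax: Taxonomy, path: str | Path) -> Path:
    """Write the taxonomy as a CSV for manual annotation.

    Membership predicates of metadata/custom sets have no column in the fixed
    header; when any exist they are written to a ``<path>.members.json``
    sidecar that :func:`read_nomenclature_table` picks up automatically.
    """
    path = Path(path)
    taxonomy_to_frame(tax).to_csv(path, index=False, encoding="utf-8")
    predicates = {
        cs.accession.render(): list(cs.predicate)
        for cs in tax.cell_sets
        if cs.predicate is not None
    }
    sidecar = path.with_suffix(path.suffix + ".members.json")
    if predicates:
        sidecar.write_text(json.dumps(predicates, indent=1, sort_keys=True), encoding="utf-8")
    elif sidecar.exists():
        sidecar.unlink()
    return path


def _split_additional(text: str) -> tuple[str, ...]:
    return tuple(t for t in (p.strip() for p in str(text).split("|")) if t)


def frame_to_taxonomy(frame: pd.DataFrame, description: str = "") -> Taxonomy:
    """Reconstruct a Taxonomy from a nomenclature-table DataFrame."""
    missing = [c for c in ("taxonomy_id", "cell_set_accession_id", "cell_set_label") if c not in frame.columns]
    if missing:
        raise BuildError(f"nomenclature table is missing required columns: {missing}")
    unknown = [c for c in frame.columns if c not in NOMENCLATURE_COLUMNS]
    if unknown:
        warnings.warn(f"ignoring unknown nomenclature table columns: {unknown}", stacklevel=2)
    frame = frame.fillna("")
    tax_ids = sorted(set(frame["taxonomy_id"].astype(str)))
    if len(tax_ids) != 1:
        raise BuildError(f"nomenclature table must describe one taxonomy, found ids {tax_ids}")
    from .model import parse_taxonomy_id  # local import to avoid cycle noise

    tax_id = parse_taxonomy_id(tax_ids[0])
    cell_sets: list[CellSet] = []
    for _, row in frame.iterrows():
        get = lambda col: str(row[col]).strip() if col in frame.columns else ""
        accession = parse_accession(get("cell_set_accession_id"))
        label = parse_label_expression(get("cell_set_label"))
        aliases: list[Alias] = []
        if get("cell_set_preferred_alias"):
            aliases.append(Alias(get("cell_set_preferred_alias"), "preferred"))
        if get("cell_set_aligned_alias"):
            aliases.append(Alias(get("cell_set_aligned_alias"), "aligned"))
        aliases.extend(Alias(t, "additional") for t in _split_additional(get("cell_set_additional_aliases")))
        kind = get("cell_set_kind") or ("leaf" if len(label.numerals()) == 1 else "node")
        cell_sets.append(CellSet(
            accession=accession,
            label=label,
            aliases=tuple(aliases),
            alias_assignee=get("cell_set_alias_assignee"),
            alias_citation=get("cell_set_alias_citation"),
            structure=get("cell_set_structure"),
            ontology_tag=get("cell_set_ontology_tag"),
            kind=kind,
            level=get("cell_set_level"),
        ))
    defaults = _infer_defaults(tax_id, cell_sets)
    return Taxonomy(tax_id, tuple(cell_sets), defaults, description)


def _infer_defaults(tax_id, cell_sets: list[CellSet]) -> TaxonomyDefaults:
    """Recover taxonomy-wide defaults from rows (modal values; leaf prefix)."""

    def modal(values: list[str]) -> str:
        values = [v for v in values if v]
        return max(set(values), key=values.count) if values else ""

    leaves = [cs for cs in cell_sets if cs.kind == "leaf"]
    prefix = leaves[0].label.prefix if leaves else (cell_sets[0].label.prefix if cell_sets else "Cluster")
    pad = leaves[0].label.pad_width if leaves else 3
    return TaxonomyDefaults(
        taxonomy_id=tax_id,
        assignee=modal([cs.alias_assignee for cs in cell_sets]),
        citation=modal([cs.alias_citation for cs in cell_sets]),
        structure=modal([cs.structure for cs in cell_sets]),
        ontology_tag=modal([cs.ontology_tag for cs in cell_sets]),
        prefix=prefix,
        pad_width=pad,
    )


def read_nomenclature_table(path: str | Path, description: str = "") -> Taxonomy:
    """Read a nomenclature CSV (tolerating a UTF-8 BOM) back to a Taxonomy."""
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8-sig")
    tax = frame_to_taxonomy(frame, description)
    sidecar = path.with_suffix(path.suffix + ".members.json")
    if sidecar.exists():
        predicates = json.loads(sidecar.read_text(encoding="utf-8"))
        updated = []
        for cs in tax.cell_sets:
            pred = predicates.get(cs.accession.render())
            if pred is not None:
                from dataclasses import replace

                cs = replace(cs, predicate=(str(pred[0]), str(pred[1])))
            updated.append(cs)
        tax = tax.with_cell_sets(updated)
    return tax
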