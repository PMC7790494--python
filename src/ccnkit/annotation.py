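"""The manual-annotation round trip: apply curated edits to a taxonomy.

Curators edit the nomenclature CSV in a spreadsheet — adding literature
aliases ("Rosehip"), aligned aliases from a reference comparison, or revised
anatomical structures — and the edited table is read back and applied here.
Edits are full-row upserts keyed by accession: a blank cell means "leave
unchanged" and the literal token ``-`` means "clear".  The assignee and
citation in an edit row are recorded as provenance on every alias that row
touches.
"""

from __future__ import annotations

import warnings
from dataclasses import replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .model import (
    Alias,
    CCNError,
    CellSet,
    CellSetAccession,
    Taxonomy,
    is_curie,
)

__all__ = ["EditError", "apply_annotations", "generalize_structure", "read_edits"]

CLEAR = "-"


class EditError(CCNError, ValueError):
    """An edits table references an unknown accession or carries bad values."""


def read_edits(path: str | Path) -> pd.DataFrame:
    """Read an edits CSV (same header as the nomenclature table, BOM tolerated)."""
    return pd.read_csv(Path(path), dtype=str, keep_default_na=False, encoding="utf-8-sig")


def _edited(current: str, cell: str) -> str:
    if cell == "":
        return current
    if cell == CLEAR:
        return ""
    return cell


def apply_annotations(
    tax: Taxonomy,
    edits: pd.DataFrame,
    strict_aligned: bool = False,
    vocabulary=None,
) -> Taxonomy:
    """Apply an edits table to a taxonomy, returning the updated copy.

    Alias, assignee, citation, structure, ontology tag and level columns are
    upserted per row; untouched fields are preserved, so applying the same
    table twice is a no-op after the first time.  Unknown accessions raise
    :class:`EditError` (new cell sets must go through
    :func:`ccnkit.builder.add_cell_set`).  With ``strict_aligned`` an aligned
    alias that does not parse under the cortical naming grammar is an error;
    otherwise it only warns.
    """
    if "cell_set_accession_id" not in edits.columns:
        raise EditError("edits table must carry a 'cell_set_accession_id' column")
    edits = edits.fillna("")
    known = {cs.accession.render() for cs in tax.cell_sets}
    unknown = [a for a in edits["cell_set_accession_id"].astype(str) if a.strip() and a.strip() not in known]
    if unknown:
        raise EditError(
            f"edits reference unknown accession(s) {sorted(set(unknown))}; "
            "new cell sets must be added with add_cell_set"
        )
    by_accession = {}
    for _, row in edits.iterrows():
        acc = str(row["cell_set_accession_id"]).strip()
        if acc:
            by_accession[acc] = row

    updated: list[CellSet] = []
    for cs in tax.cell_sets:
        row = by_accession.get(cs.accession.render())
        if row is None:
            updated.append(cs)
            continue
        get = lambda col: str(row[col]).strip() if col in edits.columns else ""
        assignee = _edited(cs.alias_assignee, get("cell_set_alias_assignee"))
        citation = _edited(cs.alias_citation, get("cell_set_alias_citation"))
        prov = {"assignee": assignee, "citation": citation}

        aliases: list[Alias] = []
        pref = _edited(cs.preferred_alias, get("cell_set_preferred_alias"))
        if pref:
            changed = pref != cs.preferred_alias
            old = cs.alias("preferred")
            aliases.append(Alias(pref, "preferred", **prov) if changed or old is None else old)
        aligned = _edited(cs.aligned_alias, get("cell_set_aligned_alias"))
        if aligned:
            if aligned != cs.aligned_alias:
                _check_aligned(aligned, strict_aligned, vocabulary)
                aliases.append(Alias(aligned, "aligned", **prov))
            else:
                aliases.append(cs.alias("aligned"))
        extra_cell = get("cell_set_additional_aliases")
        if extra_cell == "":
            aliases.extend(a for a in cs.aliases if a.role == "additional")
        elif extra_cell != CLEAR:
            texts = [t for t in (p.strip() for p in extra_cell.split("|")) if t]
            old_by_text = {a.text: a for a in cs.aliases if a.role == "additional"}
            aliases.extend(old_by_text.get(t, Alias(t, "additional", **prov)) for t in texts)

        ontology = _edited(cs.ontology_tag, get("cell_set_ontology_tag"))
        if ontology and not is_curie(ontology):
            raise EditError(f"{cs.accession.render()}: ontology tag {ontology!r} is not a CURIE")
        updated.append(replace(
            cs,
            aliases=tuple(aliases),
            alias_assignee=assignee,
            alias_citation=citation,
            structure=_edited(cs.structure, get("cell_set_structure")),
            ontology_tag=ontology,
            level=_edited(cs.level, get("cell_set_level")),
        ))
    return tax.with_cell_sets(updated)


def _check_aligned(text: str, strict: bool, vocabulary) -> None:
    from .naming import AliasParseError, default_vocabulary, parse_aligned_alias

    try:
        parse_aligned_alias(text, vocabulary or default_vocabulary())
    except AliasParseError as exc:
        if strict:
            raise EditError(f"aligned alias {text!r} fails the naming grammar: {exc}") from exc
        warnings.warn(f"aligned alias {text!r} does not follow the naming grammar: {exc}", stacklevel=3)


def generalize_structure(
    tax: Taxonomy,
    accessions: Iterable[CellSetAccession | str],
    structure: str,
    ontology_tag: str,
) -> Taxonomy:
    """Re-point listed cell sets at a broader anatomical structure.

    E.g. cell types conserved across cortical areas can be generalized from
    "middle temporal gyrus" to "Neocortex" (UBERON:0001950).  The ontology
    tag must be a CURIE; unlisted sets are untouched.
    """
    if not is_curie(ontology_tag):
        raise EditError(f"ontology tag {ontology_tag!r} is not a CURIE (expected e.g. 'UBERON:0001950')")
    wanted = {a.render() if isinstance(a, CellSetAccession) else str(a) for a in accessions}
    known = {cs.accession.render() for cs in tax.cell_sets}
    missing = wanted - known
    if missing:
        raise EditError(f"unknown accession(s): {sorted(missing)}")
    updated = [
        replace(cs, structure=structure, ontology_tag=ontology_tag)
        if cs.accession.render() in wanted else cs
        for cs in tax.cell_sets
    ]
    return tax.with_cell_sets(updated)
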