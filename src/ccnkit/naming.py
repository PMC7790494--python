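"""Validate and parse aligned aliases against the cortical naming grammar.

Aligned aliases are the controlled-vocabulary names that link matched cell
sets across taxonomies (analogous to gene symbols).  The cortical convention
names each type by properties expected to be conserved across species and
modalities:

==============  ============================  =============
class           format                        example
==============  ============================  =============
glutamatergic   [Layer] [Projection] #        ``L2/3 IT 4``
GABAergic       [Canonical gene(s)] #         ``Pvalb 3``
non-neuronal    [Cell class] #                ``Microglia 2``
historical      [Historical name] #           ``Chandelier 1``
==============  ============================  =============

The trailing ordinal ``#`` distinguishes multiple types in a class and is
optional (``Sst Chodl`` carries none).  The vocabulary — layer tokens,
projection tokens and their aliases (``CF`` for corticofugal maps to
``ET``), gene symbols, broad class terms and historical names — ships as an
editable JSON config rather than being hard-coded: the convention is a
starting point, not a closed standard.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .model import CCNError, Taxonomy

__all__ = [
    "AliasParseError",
    "Vocabulary",
    "AlignedAliasTerm",
    "default_vocabulary",
    "load_vocabulary",
    "parse_aligned_alias",
    "render_aligned_alias",
    "check_taxonomy_aliases",
]


class AliasParseError(CCNError, ValueError):
    """An aligned alias does not follow the cortical naming grammar."""


@dataclass(frozen=True)
class Vocabulary:
    """Token lists driving the aligned-alias grammar."""

    layers: tuple[str, ...]
    projections: tuple[str, ...]
    projection_aliases: dict[str, str]
    genes: tuple[str, ...]
    classes: tuple[str, ...]
    historical: tuple[str, ...]

    def canonical_gene(self, token: str) -> str | None:
        for g in self.genes:
            if g.lower() == token.lower():
                return g
        return None


@dataclass(frozen=True)
class AlignedAliasTerm:
    """A parsed aligned alias.

    ``cls`` is one of glutamatergic / GABAergic / non-neuronal / historical.
    Glutamatergic terms carry a layer and projection; GABAergic terms carry
    one or more canonical genes; the other classes carry a base term.
    """

    cls: str
    layer: str = ""
    projection: str = ""
    genes: tuple[str, ...] = ()
    base: str = ""
    ordinal: int | None = None


def load_vocabulary(path: str | Path) -> Vocabulary:
    """Load a vocabulary config from a JSON file."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    return Vocabulary(
        layers=tuple(doc.get("layers", ())),
        projections=tuple(doc.get("projections", ())),
        projection_aliases=dict(doc.get("projection_aliases", {})),
        genes=tuple(doc.get("genes", ())),
        classes=tuple(doc.get("classes", ())),
        historical=tuple(doc.get("historical", ())),
    )


def default_vocabulary() -> Vocabulary:
    """The vocabulary bundled with the package (``data/vocabulary.json``)."""
    with resources.as_file(resources.files("ccnkit").joinpath("data/vocabulary.json")) as p:
        return load_vocabulary(p)


_ORDINAL_RE = re.compile(r"^\d+$")


def _normalize(text: str) -> str:
    # "L6 CT_1" and "L6 CT 1" are the same name; canonical form uses a space.
    text = re.sub(r"_(?=\d+$)", " ", text.strip())
    return re.sub(r"\s+", " ", text)


def parse_aligned_alias(text: str, vocabulary: Vocabulary | None = None) -> AlignedAliasTerm:
    """Parse an aligned alias, or raise :class:`AliasParseError` naming the
    first token that fails.

    Class is decided by the leading token: a layer token starts a
    glutamatergic name (layer and projection both mandatory), a gene token a
    GABAergic name, a cell class term a non-neuronal name, a historical term
    a historical name.  Matching is case-insensitive for genes (canonicalized
    to the config's casing) and exact for the rest.
    """
    vocab = vocabulary or default_vocabulary()
    text = _normalize(text)
    if not text:
        raise AliasParseError("empty aligned alias")
    tokens = text.split(" ")
    ordinal: int | None = None
    if len(tokens) > 1 and _ORDINAL_RE.match(tokens[-1]):
        ordinal = int(tokens[-1])
        tokens = tokens[:-1]
    if not tokens or _ORDINAL_RE.match(tokens[0]):
        raise AliasParseError(f"{text!r}: a name cannot start with the ordinal")

    head = tokens[0]
    if head in vocab.layers:
        if len(tokens) < 2:
            raise AliasParseError(f"{text!r}: glutamatergic name lacks a projection after layer {head!r}")
        proj = tokens[1]
        proj = vocab.projection_aliases.get(proj, proj)
        if proj not in vocab.projections:
            raise AliasParseError(f"{text!r}: unknown projection token {tokens[1]!r}")
        if len(tokens) > 2:
            raise AliasParseError(f"{text!r}: unexpected token {tokens[2]!r} after projection")
        return AlignedAliasTerm("glutamatergic", layer=head, projection=proj, ordinal=ordinal)

    if vocab.canonical_gene(head):
        genes = []
        for tok in tokens:
            g = vocab.canonical_gene(tok)
            if g is None:
                raise AliasParseError(f"{text!r}: unknown gene token {tok!r}")
            genes.append(g)
        return AlignedAliasTerm("GABAergic", genes=tuple(genes), ordinal=ordinal)

    base = " ".join(tokens)
    for cls, terms in (("non-neuronal", vocab.classes), ("historical", vocab.historical)):
        for term in terms:
            if term.lower() == base.lower():
                return AlignedAliasTerm(cls, base=term, ordinal=ordinal)
    raise AliasParseError(f"{text!r}: unknown token {head!r}")


def render_aligned_alias(term: AlignedAliasTerm) -> str:
    """Canonical text of a parsed alias (space-separated, config casing)."""
    if term.cls == "glutamatergic":
        parts = [term.layer, term.projection]
    elif term.cls == "GABAergic":
        parts = list(term.genes)
    else:
        parts = [term.base]
    if term.ordinal is not None:
        parts.append(str(term.ordinal))
    return " ".join(parts)


def check_taxonomy_aliases(tax: Taxonomy, vocabulary: Vocabulary | None = None) -> pd.DataFrame:
    """Per-cell-set report of aligned alias conformance.

    Columns: accession, aligned alias, status (``ok`` / ``unassigned`` /
    ``invalid``), parsed class, canonical form, and the parse diagnostic for
    failures.  ``report.attrs["class_counts"]`` summarizes counts by class.
    """
    vocab = vocabulary or default_vocabulary()
    rows = []
    for cs in tax.cell_sets:
        alias = cs.aligned_alias
        if not alias:
            rows.append((cs.accession.render(), "", "unassigned", "", "", ""))
            continue
        try:
            term = parse_aligned_alias(alias, vocab)
            rows.append((cs.accession.render(), alias, "ok", term.cls, render_aligned_alias(term), ""))
        except AliasParseError as exc:
            rows.append((cs.accession.render(), alias, "invalid", "", "", str(exc)))
    report = pd.DataFrame(
        rows,
        columns=["cell_set_accession_id", "aligned_alias", "status", "cls", "canonical", "diagnostic"],
    )
    counts = report.loc[report["status"] == "ok", "cls"].value_counts().to_dict()
    counts["unassigned"] = int((report["status"] == "unassigned").sum())
    counts["invalid"] = int((report["status"] == "invalid").sum())
    report.attrs["class_counts"] = counts
    return report
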