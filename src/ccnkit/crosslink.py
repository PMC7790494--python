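"""Link cell sets across taxonomies via aligned aliases and label references.

Two mechanisms connect cell sets from different taxonomies without touching
expression data: (a) matched cell sets share an identical aligned alias
drawn from the common controlled vocabulary; (b) an additional alias of the
form ``"<label expression> in <taxonomy id>"`` (e.g. ``"RNA-seq 040 in
CCN201912131"``) explicitly names the provisional types of another taxonomy
that a cell set contains.  A :class:`Registry` holds any number of
taxonomies, and :func:`build_link_graph` materializes both edge kinds as an
undirected networkx graph whose connected components are the
cross-taxonomy groups of matched cell sets.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import pandas as pd

from .builder import frame_to_taxonomy, read_nomenclature_table
from .model import (
    Alias,
    CCNError,
    CellSetAccession,
    ParseError,
    Taxonomy,
    TaxonomyId,
    expand_label,
    parse_label_expression,
    parse_taxonomy_id,
)

__all__ = [
    "AliasReference",
    "Registry",
    "RegistryError",
    "parse_alias_reference",
    "build_link_graph",
    "component_report",
    "transfer_aligned_aliases",
]

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ("taxonomy_id", "description", "citation", "file")


class RegistryError(CCNError, ValueError):
    """The registry would violate global uniqueness."""


@dataclass(frozen=True)
class AliasReference:
    """A parsed cross-taxonomy reference: target taxonomy + leaf labels."""

    target_taxonomy: TaxonomyId
    labels: tuple[str, ...]


_REFERENCE_TRIGGER = re.compile(r"\bin\s+(CCN\S*)\s*$")


def parse_alias_reference(text: str) -> AliasReference | None:
    """Recognize ``"<label expression> in <taxonomy id>"`` additional aliases.

    Returns the reference with its labels expanded to individual provisional
    types, ``None`` for ordinary aliases ("Long-range projecting Sst"), and
    raises :class:`~ccnkit.model.ParseError` when the pattern is present but
    the taxonomy id or label expression is malformed.
    """
    m = _REFERENCE_TRIGGER.search(text.strip())
    if not m:
        return None
    target = parse_taxonomy_id(m.group(1))
    expr_text = text.strip()[: m.start()].strip()
    expr = parse_label_expression(expr_text)
    return AliasReference(target, tuple(expand_label(expr)))


@dataclass
class Registry:
    """A collection of taxonomies with applied CCN, keyed by taxonomy id."""

    taxonomies: dict[str, Taxonomy] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def add(self, tax: Taxonomy, source: str = "") -> None:
        key = tax.id.render()
        if key in self.taxonomies:
            raise RegistryError(f"taxonomy id {key} already registered")
        incoming = {cs.accession.render() for cs in tax.cell_sets}
        for other in self.taxonomies.values():
            clash = incoming & {cs.accession.render() for cs in other.cell_sets}
            if clash:
                raise RegistryError(f"accessions already registered elsewhere: {sorted(clash)[:5]}")
        self.taxonomies[key] = tax
        self.provenance[key] = source

    def __len__(self) -> int:
        return len(self.taxonomies)

    def __contains__(self, taxonomy_id: str) -> bool:
        return taxonomy_id in self.taxonomies

    @classmethod
    def from_manifest(cls, path: str | Path) -> "Registry":
        """Load taxonomies listed in a manifest CSV
        (``taxonomy_id,description,citation,file``).

        Rows whose ``file`` is empty or missing become metadata-only stub
        taxonomies (id + description, no cell sets); otherwise the referenced
        nomenclature table is read relative to the manifest's directory.
        """
        path = Path(path)
        frame = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8-sig")
        if "taxonomy_id" not in frame.columns:
            raise RegistryError(f"{path}: manifest lacks a 'taxonomy_id' column")
        registry = cls()
        for _, row in frame.iterrows():
            tax_id = parse_taxonomy_id(str(row["taxonomy_id"]).strip())
            file_ref = str(row.get("file", "")).strip()
            description = str(row.get("description", "")).strip()
            if file_ref:
                tax = read_nomenclature_table(path.parent / file_ref, description)
                if tax.id != tax_id:
                    raise RegistryError(
                        f"{file_ref}: table taxonomy id {tax.id.render()} != manifest id {tax_id.render()}"
                    )
            else:
                tax = Taxonomy(tax_id, (), None, description)
            registry.add(tax, source=file_ref or str(path))
        return registry

    @classmethod
    def from_records(cls, frame: pd.DataFrame) -> "Registry":
        """Build a registry from a multi-taxonomy nomenclature table, one
        (possibly partial) taxonomy per distinct ``taxonomy_id``."""
        registry = cls()
        for tax_id, group in frame.groupby("taxonomy_id", sort=True):
            registry.add(frame_to_taxonomy(group.reset_index(drop=True)))
        return registry


def _node_key(tax: Taxonomy, cs) -> tuple[str, str]:
    return (tax.id.render(), cs.accession.render())


def build_link_graph(
    registry: Registry,
    cell_memberships: dict[str, "pd.DataFrame"] | None = None,
) -> nx.Graph:
    """The undirected cross-taxonomy link graph over (taxonomy, accession) nodes.

    Edges (tagged with ``kind``):

    * ``alias`` — two cell sets in different taxonomies share an identical
      non-empty aligned alias (exact string after whitespace normalization).
    * ``reference`` — a cell set's additional alias names provisional types
      of another registered taxonomy; one edge per resolvable target leaf.
      A reference resolves to the cell sets whose labels cover exactly the
      referenced numerals (the leaves, not any node spanning them).
      References to absent taxonomies or labels are logged and skipped.
    * ``co_cell`` — optional: given per-taxonomy membership matrices over a
      shared dataset (``cell_memberships``: taxonomy id → cells × accessions
      frame), two cell sets in different taxonomies whose member cell-id
      sets are identical and non-empty are linked.
    """
    graph = nx.Graph()
    by_alias: dict[str, list[tuple[str, str]]] = {}
    # label text (normalized per prefix+numerals) -> node key, per taxonomy
    label_index: dict[str, dict[tuple[str, tuple[int, ...]], tuple[str, str]]] = {}
    for tax in registry.taxonomies.values():
        label_index[tax.id.render()] = {}
        for cs in tax.cell_sets:
            key = _node_key(tax, cs)
            graph.add_node(
                key,
                preferred_alias=cs.preferred_alias,
                aligned_alias=cs.aligned_alias,
                label=cs.label.render(),
                kind=cs.kind,
            )
            aligned = " ".join(cs.aligned_alias.split())
            if aligned:
                by_alias.setdefault(aligned, []).append(key)
            label_index[tax.id.render()][(cs.label.prefix, tuple(cs.label.numerals()))] = key

    for alias, nodes in by_alias.items():
        for i, a in enumerate(nodes):
            for b in nodes[i + 1:]:
                if a[0] != b[0]:
                    graph.add_edge(a, b, kind="alias", alias=alias)

    for tax in registry.taxonomies.values():
        for cs in tax.cell_sets:
            for text in cs.additional_aliases:
                try:
                    ref = parse_alias_reference(text)
                except ParseError as exc:
                    logger.warning("unparseable alias reference %r: %s", text, exc)
                    continue
                if ref is None:
                    continue
                target_key = ref.target_taxonomy.render()
                if target_key not in registry.taxonomies:
                    logger.info("reference %r: taxonomy %s not in registry; skipped", text, target_key)
                    continue
                index = label_index[target_key]
                for label in ref.labels:
                    expr = parse_label_expression(label)
                    hit = index.get((expr.prefix, tuple(expr.numerals())))
                    if hit is None:
                        logger.info("reference %r: label %r not found in %s; skipped", text, label, target_key)
                        continue
                    graph.add_edge(_node_key(tax, cs), hit, kind="reference", reference=text)

    if cell_memberships:
        _add_co_cell_edges(graph, cell_memberships)
    return graph


def _add_co_cell_edges(graph: nx.Graph, memberships: dict[str, pd.DataFrame]) -> None:
    sets: list[tuple[tuple[str, str], frozenset[str]]] = []
    for tax_id, frame in memberships.items():
        for accession in frame.columns:
            members = frozenset(frame.index[frame[accession] > 0])
            if members:
                sets.append(((tax_id, accession), members))
    for i, (a, ma) in enumerate(sets):
        for b, mb in sets[i + 1:]:
            if a[0] != b[0] and ma == mb:
                if graph.has_node(a) and graph.has_node(b):
                    graph.add_edge(a, b, kind="co_cell")


def component_report(graph: nx.Graph) -> pd.DataFrame:
    """Connected components as a flat table
    (``component_id,taxonomy_id,cell_set_accession_id,preferred_alias,aligned_alias``).

    Components are numbered deterministically by their smallest accession.
    """
    components = sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    rows = []
    for cid, comp in enumerate(components, start=1):
        for tax_id, accession in sorted(comp):
            data = graph.nodes[(tax_id, accession)]
            rows.append({
                "component_id": cid,
                "taxonomy_id": tax_id,
                "cell_set_accession_id": accession,
                "preferred_alias": data.get("preferred_alias", ""),
                "aligned_alias": data.get("aligned_alias", ""),
            })
    return pd.DataFrame(
        rows,
        columns=["component_id", "taxonomy_id", "cell_set_accession_id", "preferred_alias", "aligned_alias"],
    )


def transfer_aligned_aliases(
    source: Taxonomy,
    target: Taxonomy,
    correspondence: dict[str, str],
) -> Taxonomy:
    """Copy aligned aliases from a reference taxonomy onto matched cell sets.

    ``correspondence`` maps target accession → source accession and comes
    from an upstream computational alignment (alignment itself is outside
    the CCN).  Each matched target set gains the source set's aligned alias
    text with the source taxonomy id recorded as the alias citation;
    accessions absent on either side are an error.  Idempotent for a fixed
    correspondence.
    """
    source_by_acc = {cs.accession.render(): cs for cs in source.cell_sets}
    target_by_acc = {cs.accession.render(): cs for cs in target.cell_sets}
    missing_t = sorted(set(correspondence) - set(target_by_acc))
    missing_s = sorted(set(correspondence.values()) - set(source_by_acc))
    if missing_t or missing_s:
        raise RegistryError(
            f"correspondence references unknown accessions (target: {missing_t[:5]}, source: {missing_s[:5]})"
        )
    updated = []
    for cs in target.cell_sets:
        src_acc = correspondence.get(cs.accession.render())
        src_alias = source_by_acc[src_acc].aligned_alias if src_acc else ""
        if src_acc and src_alias:
            aliases = tuple(a for a in cs.aliases if a.role != "aligned")
            aliases += (Alias(src_alias, "aligned", citation=source.id.render()),)
            cs = replace(cs, aliases=aliases)
        updated.append(cs)
    return target.with_cell_sets(updated)
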