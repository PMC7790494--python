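"""Read, traverse, annotate and write hierarchical cell type taxonomies.

A dendrogram organizes provisional cell types as terminal leaves and groups
of similar types as internal nodes; both become cell sets when the CCN is
applied.  Trees are serialized as canonical JSON (sorted keys, UTF-8,
explicit ``children`` arrays); the schema ships in
``ccnkit/data/dendrogram.schema.json``.  Trees need not be binary — any
internal node with two or more children is legal — and taxonomies without a
dendrogram (non-hierarchical community structure) simply bypass this module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator

from .model import CCNError, CellSetAccession, Taxonomy

__all__ = [
    "DendNode",
    "SchemaError",
    "AnnotationError",
    "read_dendrogram",
    "write_dendrogram",
    "leaf_order",
    "node_leaf_spans",
    "annotate_dendrogram",
    "render_dendrogram",
]

_ANNOTATION_KEYS = (
    "cell_set_accession",
    "cell_set_label",
    "cell_set_preferred_alias",
    "cell_set_aligned_alias",
)


class SchemaError(CCNError, ValueError):
    """The JSON document does not conform to the dendrogram schema."""


class AnnotationError(CCNError, ValueError):
    """A dendrogram node has no matching cell set in the taxonomy."""


@dataclass
class DendNode:
    """One node of the taxonomy tree.

    Leaves carry the publication's cluster name in ``original_label`` and
    have no children; internal nodes have at least two.  After annotation
    each node additionally carries its cell set accession, label and alias
    fields.
    """

    node_id: str
    children: list["DendNode"] = field(default_factory=list)
    original_label: str = ""
    cell_set_accession: str = ""
    cell_set_label: str = ""
    cell_set_preferred_alias: str = ""
    cell_set_aligned_alias: str = ""

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["DendNode"]:
        """Depth-first pre-order traversal."""
        yield self
        for child in self.children:
            yield from child.walk()

    def n_leaves(self) -> int:
        return sum(1 for n in self.walk() if n.is_leaf)


def _node_from_dict(doc: dict, seen_ids: set[str], path: str) -> DendNode:
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: node must be a JSON object, got {type(doc).__name__}")
    node_id = doc.get("node_id")
    if not isinstance(node_id, str) or not node_id:
        raise SchemaError(f"{path}: missing or empty 'node_id'")
    if node_id in seen_ids:
        raise SchemaError(f"{path}: duplicate node_id {node_id!r}")
    seen_ids.add(node_id)
    children_doc = doc.get("children", [])
    if not isinstance(children_doc, list):
        raise SchemaError(f"{path}: 'children' must be an array")
    node = DendNode(
        node_id=node_id,
        original_label=str(doc.get("original_label") or ""),
        cell_set_accession=str(doc.get("cell_set_accession") or ""),
        cell_set_label=str(doc.get("cell_set_label") or ""),
        cell_set_preferred_alias=str(doc.get("cell_set_preferred_alias") or ""),
        cell_set_aligned_alias=str(doc.get("cell_set_aligned_alias") or ""),
    )
    for i, child_doc in enumerate(children_doc):
        node.children.append(_node_from_dict(child_doc, seen_ids, f"{path}/children[{i}]"))
    if node.is_leaf and not node.original_label and not node.cell_set_label:
        raise SchemaError(f"{path}: leaf {node_id!r} has no 'original_label'")
    if not node.is_leaf and len(node.children) < 2:
        raise SchemaError(f"{path}: internal node {node_id!r} must have >= 2 children")
    return node


def read_dendrogram(source: str | Path | IO[str] | dict) -> DendNode:
    """Parse a dendrogram JSON document (path, file object or dict) to its root.

    Raises :class:`SchemaError` on duplicate node ids, leaves without labels,
    or internal nodes with fewer than two children.  Because the format is a
    JSON tree with ids checked for uniqueness, cycles are impossible by
    construction.
    """
    if isinstance(source, dict):
        doc = source
    elif isinstance(source, (str, Path)):
        doc = json.loads(Path(source).read_text(encoding="utf-8"))
    else:
        doc = json.load(source)
    return _node_from_dict(doc, set(), "$")


def _node_to_dict(node: DendNode) -> dict:
    doc: dict = {"node_id": node.node_id}
    if node.original_label:
        doc["original_label"] = node.original_label
    for key in _ANNOTATION_KEYS:
        value = getattr(node, key)
        if value:
            doc[key] = value
    doc["children"] = [_node_to_dict(c) for c in node.children]
    return doc


def write_dendrogram(root: DendNode, target: str | Path | IO[str] | None = None) -> str:
    """Serialize a tree to canonical JSON (sorted keys, 1-space free, UTF-8).

    Returns the JSON text; when ``target`` is given the text is also written
    there.  read∘write is the identity on topology, leaf order and all
    annotation fields.
    """
    text = json.dumps(_node_to_dict(root), sort_keys=True, ensure_ascii=False, indent=1)
    if isinstance(target, (str, Path)):
        Path(target).write_text(text, encoding="utf-8")
    elif target is not None:
        target.write(text)
    return text


def leaf_order(root: DendNode) -> list[DendNode]:
    """Left-to-right depth-first sequence of leaves (the numbering order)."""
    return [n for n in root.walk() if n.is_leaf]


def node_leaf_spans(root: DendNode) -> dict[str, frozenset[int]]:
    """Map every node id to the 1-based positions of its descendant leaves.

    A leaf maps to its own position; an internal node's span is the union of
    its children's spans (siblings are disjoint by tree structure).
    """
    positions = {leaf.node_id: i for i, leaf in enumerate(leaf_order(root), start=1)}
    spans: dict[str, frozenset[int]] = {}

    def visit(node: DendNode) -> frozenset[int]:
        if node.is_leaf:
            span = frozenset({positions[node.node_id]})
        else:
            span = frozenset().union(*(visit(c) for c in node.children))
        spans[node.node_id] = span
        return span

    visit(root)
    return spans


def annotate_dendrogram(root: DendNode, tax: Taxonomy) -> DendNode:
    """Attach each node's cell set accession, label and aliases in place.

    Nodes are matched to cell sets by leaf span: the cell set whose label
    expression covers exactly the node's descendant leaf positions.  Custom
    and metadata sets never match (they are not part of the tree).  Raises
    :class:`AnnotationError` listing every orphan node.  Idempotent.
    """
    spans = node_leaf_spans(root)
    by_span: dict[frozenset[int], object] = {}
    for cs in tax.cell_sets:
        if cs.kind in ("leaf", "node"):
            by_span.setdefault(frozenset(cs.label.numerals()), cs)
    orphans = [n.node_id for n in root.walk() if spans[n.node_id] not in by_span]
    if orphans:
        raise AnnotationError(
            f"no matching cell set for {len(orphans)} node(s): {', '.join(orphans[:10])}"
        )
    for node in root.walk():
        cs = by_span[spans[node.node_id]]
        node.cell_set_accession = cs.accession.render()
        node.cell_set_label = cs.label.render()
        node.cell_set_preferred_alias = cs.preferred_alias
        node.cell_set_aligned_alias = cs.aligned_alias
    return root


def render_dendrogram(root: DendNode, path: str | Path) -> None:
    """Draw the annotated tree to a figure file (PDF/SVG/PNG by extension).

    Cosmetic output for inspection; the JSON serialization is the canonical
    form.  Requires matplotlib.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    leaves = leaf_order(root)
    xpos = {leaf.node_id: float(i) for i, leaf in enumerate(leaves, start=1)}
    depth: dict[str, int] = {}

    def measure(node: DendNode, d: int) -> int:
        depth[node.node_id] = d
        return max([d] + [measure(c, d + 1) for c in node.children])

    max_depth = measure(root, 0)
    ypos: dict[str, float] = {}

    def place(node: DendNode) -> float:
        if node.is_leaf:
            ypos[node.node_id] = 0.0
            return xpos[node.node_id]
        xs = [place(c) for c in node.children]
        x = sum(xs) / len(xs)
        xpos[node.node_id] = x
        ypos[node.node_id] = float(max_depth - depth[node.node_id])
        return x

    place(root)
    fig, ax = plt.subplots(figsize=(max(6.0, 0.3 * len(leaves)), 4.0))
    for node in root.walk():
        for child in node.children:
            ax.plot(
                [xpos[node.node_id], xpos[child.node_id], xpos[child.node_id]],
                [ypos[node.node_id], ypos[node.node_id], ypos[child.node_id]],
                color="0.3", linewidth=0.8,
            )
        if not node.is_leaf and node.cell_set_preferred_alias:
            ax.plot(xpos[node.node_id], ypos[node.node_id], "o", color="teal", markersize=4)
    for leaf in leaves:
        name = leaf.cell_set_preferred_alias or leaf.original_label
        ax.text(xpos[leaf.node_id], -0.1, name, rotation=90, ha="center", va="top", fontsize=6)
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
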