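"""Building taxonomies from dendrograms and the nomenclature-table CSV."""

import pandas as pd
import pytest

from conftest import caterpillar_tree, random_tree
from ccnkit.builder import (
    BuildError,
    NOMENCLATURE_COLUMNS,
    add_cell_set,
    build_taxonomy,
    read_nomenclature_table,
    taxonomy_to_frame,
    write_nomenclature_table,
)
from ccnkit.dendrogram import DendNode, leaf_order, node_leaf_spans
from ccnkit.fixtures import MTG_DEFAULTS
from ccnkit.model import TaxonomyDefaults, parse_taxonomy_id, validate_taxonomy

DEFAULTS = TaxonomyDefaults(
    parse_taxonomy_id("CCN202001010"),
    assignee="A. Curator",
    citation="10.1000/example",
    structure="neocortex",
    ontology_tag="UBERON:0001950",
    prefix="SIM",
)


def test_leaves_keep_original_names_as_preferred_alias(mtg_taxonomy):
    leaf1 = mtg_taxonomy.cell_sets[0]
    assert leaf1.accession.render() == "CS201908210_1"
    assert leaf1.label.render() == "MTG 001"
    assert leaf1.preferred_alias == "Inh L1-2 PAX6 CDH12"
    assert leaf1.kind == "leaf"


def test_node_over_first_six_leaves_gets_range_label(mtg_taxonomy):
    labels = {cs.label.render() for cs in mtg_taxonomy.cell_sets if cs.kind == "node"}
    assert "MTG 001-006" in labels
    node = next(cs for cs in mtg_taxonomy.cell_sets if cs.label.render() == "MTG 001-006")
    assert node.preferred_alias == ""  # internal nodes start unnamed
    assert node.accession.number > 75  # numbered after all leaves


def test_defaults_propagate_to_every_cell_set(mtg_taxonomy):
    for cs in mtg_taxonomy.cell_sets:
        assert cs.structure == "middle temporal gyrus"
        assert cs.ontology_tag == "UBERON:0002771"
        assert cs.alias_assignee == "Trygve Bakken"
        assert cs.alias_citation == "10.1038/s41586-019-1506-7"


def test_single_leaf_tree_builds_one_cell_set():
    root = DendNode("only", original_label="The Type")
    tax = build_taxonomy(DEFAULTS, root)
    assert len(tax) == 1
    only = tax.cell_sets[0]
    assert only.accession.number == 1 and only.label.render() == "SIM 001"


def test_count_and_numbering_invariants():
    for seed in range(8):
        root = random_tree(n_leaves=9 + seed, seed=seed, branching=2 + seed % 3)
        tax = build_taxonomy(DEFAULTS, root)
        leaves = leaf_order(root)
        internal = sum(1 for n in root.walk() if not n.is_leaf)
        assert len(tax) == len(leaves) + internal
        # leaf accession number == leaf position
        for i, cs in enumerate(tax.leaves(), start=1):
            assert cs.accession.number == i and cs.label.numerals() == [i]
        # the set of node spans reconstructs the tree's span set
        tree_spans = {frozenset(s) for s in node_leaf_spans(root).values()}
        built_spans = {frozenset(cs.label.numerals()) for cs in tax.cell_sets}
        assert built_spans == tree_spans
        assert validate_taxonomy(tax) == []


def test_duplicate_leaf_labels_rejected():
    root = caterpillar_tree(["same", "same", "other"])
    with pytest.raises(BuildError, match="duplicate leaf labels"):
        build_taxonomy(DEFAULTS, root)


def test_add_metadata_set_numbers_and_labels():
    tax = build_taxonomy(DEFAULTS, caterpillar_tree([f"t{i}" for i in range(5)]))
    before = len(tax)
    tax = add_cell_set(tax, kind="metadata", preferred_alias="Neurosurgical",
                       predicate=("tissue", "neurosurgical"))
    new = tax.cell_sets[-1]
    assert new.label.render() == "Metadata 1"
    assert new.preferred_alias == "Neurosurgical"
    assert new.accession.number == tax.max_number() == before + 1  # 5 leaves + 4 nodes -> 10


def test_added_sets_extend_accessions_by_max_plus_one():
    tax = build_taxonomy(DEFAULTS, caterpillar_tree([f"t{i}" for i in range(6)]))
    # 6 leaves + 5 internal nodes on a caterpillar = 11 existing sets
    assert len(tax) == 11
    start = tax.max_number()
    for k, members in enumerate([{1, 3}, {2, 4, 5}, {4, 6}], start=1):
        tax = add_cell_set(tax, members=members, kind="custom", preferred_alias=f"group {k}")
        assert tax.cell_sets[-1].accession.number == start + k
    assert len(tax) == 11 + 3


def test_custom_union_duplicates_node_membership_with_distinct_accession():
    tax = build_taxonomy(MTG_DEFAULTS, caterpillar_tree([f"t{i}" for i in range(6)]))
    node = next(cs for cs in tax.cell_sets if cs.label.render() == "MTG 001-006")
    tax2 = add_cell_set(tax, members="Grouped 001-006", kind="custom")
    custom = tax2.cell_sets[-1]
    assert set(custom.label.numerals()) == set(node.label.numerals())
    assert custom.accession != node.accession


def test_label_collision_rejected():
    tax = build_taxonomy(DEFAULTS, caterpillar_tree(["a", "b", "c"]))
    with pytest.raises(BuildError, match="label collision"):
        add_cell_set(tax, members="SIM 001-003", kind="custom")


def test_unknown_leaf_numerals_rejected():
    tax = build_taxonomy(DEFAULTS, caterpillar_tree(["a", "b", "c"]))
    with pytest.raises(BuildError, match="unknown leaf numerals"):
        add_cell_set(tax, members={2, 99}, kind="custom")


def test_csv_header_is_bit_exact(mtg_taxonomy, tmp_path):
    path = tmp_path / "nomenclature.csv"
    write_nomenclature_table(mtg_taxonomy, path)
    header = path.read_text(encoding="utf-8").splitlines()[0]
    assert header == ",".join(NOMENCLATURE_COLUMNS)


def test_csv_round_trip_is_lossless(mtg_taxonomy, tmp_path):
    path = tmp_path / "nomenclature.csv"
    write_nomenclature_table(mtg_taxonomy, path)
    back = read_nomenclature_table(path)
    assert back.id == mtg_taxonomy.id
    assert back.cell_sets == mtg_taxonomy.cell_sets
    assert back.defaults == mtg_taxonomy.defaults


def test_csv_round_trip_keeps_metadata_predicates(tmp_path):
    tax = build_taxonomy(DEFAULTS, caterpillar_tree(["a", "b", "c"]))
    tax = add_cell_set(tax, kind="metadata", preferred_alias="Neurosurgical",
                       predicate=("tissue", "neurosurgical"))
    path = tmp_path / "nomenclature.csv"
    write_nomenclature_table(tax, path)
    back = read_nomenclature_table(path)
    assert back.cell_sets[-1].predicate == ("tissue", "neurosurgical")


def test_en_dash_table_parses_like_hyphen_table(tmp_path):
    tax = build_taxonomy(DEFAULTS, caterpillar_tree([f"t{i}" for i in range(6)]))
    hyphen = tmp_path / "hyphen.csv"
    write_nomenclature_table(tax, hyphen)
    endash = tmp_path / "endash.csv"
    endash.write_text(hyphen.read_text(encoding="utf-8").replace("-0", "–0"), encoding="utf-8")
    a, b = read_nomenclature_table(hyphen), read_nomenclature_table(endash)
    assert a.cell_sets == b.cell_sets


def test_eight_bundled_records_parse_from_csv():
    from ccnkit.builder import frame_to_taxonomy
    from ccnkit.fixtures import reference_bundle

    frame = reference_bundle().sst_chodl
    taxonomies = [frame_to_taxonomy(g.reset_index(drop=True)) for _, g in frame.groupby("taxonomy_id")]
    cell_sets = [cs for t in taxonomies for cs in t.cell_sets]
    assert len(cell_sets) == 8
    assert all(cs.structure == "primary motor cortex" for cs in cell_sets)


def test_unknown_columns_warn_and_missing_required_fail(tmp_path):
    frame = taxonomy_to_frame(build_taxonomy(DEFAULTS, caterpillar_tree(["a", "b"])))
    frame["surprise"] = "x"
    path = tmp_path / "extra.csv"
    frame.to_csv(path, index=False)
    with pytest.warns(UserWarning, match="surprise"):
        read_nomenclature_table(path)
    bad = tmp_path / "bad.csv"
    frame.drop(columns=["cell_set_label", "surprise"]).to_csv(bad, index=False)
    with pytest.raises(BuildError, match="missing required columns"):
        read_nomenclature_table(bad)
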