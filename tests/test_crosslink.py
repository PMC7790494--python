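"""Cross-taxonomy linking: alias references, the link graph, alias transfer."""

import itertools

import networkx as nx
import pandas as pd
import pytest

from conftest import caterpillar_tree
from ccnkit.builder import build_taxonomy, frame_to_taxonomy
from ccnkit.crosslink import (
    Registry,
    RegistryError,
    build_link_graph,
    component_report,
    parse_alias_reference,
    transfer_aligned_aliases,
)
from ccnkit.fixtures import data_path, reference_bundle
from ccnkit.model import Alias, ParseError, TaxonomyDefaults, parse_taxonomy_id


def test_reference_with_single_label():
    ref = parse_alias_reference("RNA-seq 040 in CCN201912131")
    assert ref.target_taxonomy.render() == "CCN201912131"
    assert ref.labels == ("RNA-seq 040",)


def test_reference_with_ranges_expands_to_seven_labels():
    ref = parse_alias_reference("RNA-seq 040, 046-047, 050-052, 068 in CCN201912131")
    assert len(ref.labels) == 7
    assert ref.labels[0] == "RNA-seq 040" and ref.labels[-1] == "RNA-seq 068"


def test_plain_alias_is_not_a_reference():
    assert parse_alias_reference("Long-range projecting Sst") is None


def test_reference_with_malformed_taxonomy_id_errors():
    with pytest.raises(ParseError):
        parse_alias_reference("RNA-seq 040 in CCN2019")


@pytest.fixture
def sst_registry():
    return Registry.from_records(reference_bundle().sst_chodl)


def test_sst_chodl_records_form_one_component(sst_registry):
    graph = build_link_graph(sst_registry)
    component = nx.node_connected_component(graph, ("CCN201912131", "CS201912131_40"))
    assert len(component) == 8  # every listed cell set is reachable


def test_reference_edges_link_epigenome_sets_to_transcriptome_leaves(sst_registry):
    graph = build_link_graph(sst_registry)
    # The DNA-methylation set without an 'Sst Chodl' aligned alias is tied in
    # purely by its label reference into the transcriptomics taxonomy.
    edge = graph.get_edge_data(("CCN202002272", "CS202002272_12"), ("CCN201912131", "CS201912131_40"))
    assert edge is not None and edge["kind"] == "reference"


def test_component_report_layout(sst_registry, tmp_path):
    report = component_report(build_link_graph(sst_registry))
    assert list(report.columns) == [
        "component_id", "taxonomy_id", "cell_set_accession_id", "preferred_alias", "aligned_alias",
    ]
    assert (report["component_id"] == 1).sum() == 8


def test_taxonomies_without_shared_aliases_stay_unlinked():
    d1 = TaxonomyDefaults(parse_taxonomy_id("CCN202001010"), prefix="A")
    d2 = TaxonomyDefaults(parse_taxonomy_id("CCN202001011"), prefix="B")
    registry = Registry()
    registry.add(build_taxonomy(d1, caterpillar_tree(["x", "y"])))
    registry.add(build_taxonomy(d2, caterpillar_tree(["p", "q"])))
    graph = build_link_graph(registry)
    assert graph.number_of_edges() == 0
    assert graph.number_of_nodes() == 6


def test_duplicate_taxonomy_id_rejected(sst_registry):
    with pytest.raises(RegistryError, match="already registered"):
        sst_registry.add(build_taxonomy(
            TaxonomyDefaults(parse_taxonomy_id("CCN201912131"), prefix="X"),
            caterpillar_tree(["a", "b"]),
        ))


def test_manifest_ingest_counts_taxonomies():
    registry = Registry.from_manifest(data_path("taxonomy_registry.csv"))
    assert len(registry) == 18
    assert "CCN201810310" in registry


def test_components_equal_brute_force_closure_on_random_registries():
    import random

    rng = random.Random(5)
    alias_pool = ["Pvalb 1", "Sst 1", "Vip 2", "Lamp5 1", "Sncg 3", ""]
    for trial in range(15):
        registry = Registry()
        for t in range(rng.randint(2, 4)):
            defaults = TaxonomyDefaults(parse_taxonomy_id(f"CCN20200301{t}"), prefix=f"T{t}")
            tax = build_taxonomy(defaults, caterpillar_tree([f"x{t}_{i}" for i in range(rng.randint(2, 5))]))
            updated = []
            for cs in tax.cell_sets:
                alias = rng.choice(alias_pool)
                if alias:
                    cs = type(cs)(**{**cs.__dict__, "aliases": (Alias(alias, "aligned"),)})
                updated.append(cs)
            registry.add(tax.with_cell_sets(updated))
        graph = build_link_graph(registry)
        # brute-force transitive closure over explicit pairwise alias matches
        nodes = [(tid, cs) for tid, tax in registry.taxonomies.items() for cs in tax.cell_sets]
        parent = {i: i for i in range(len(nodes))}

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, j in itertools.combinations(range(len(nodes)), 2):
            (ta, a), (tb, b) = nodes[i], nodes[j]
            if ta != tb and a.aligned_alias and a.aligned_alias == b.aligned_alias:
                parent[find(i)] = find(j)
        expected = {}
        for i, (tid, cs) in enumerate(nodes):
            expected.setdefault(find(i), set()).add((tid, cs.accession.render()))
        got = {frozenset(c) for c in nx.connected_components(graph)}
        assert got == {frozenset(c) for c in expected.values()}


def test_co_cell_edges_link_identical_member_sets():
    d1 = TaxonomyDefaults(parse_taxonomy_id("CCN202001010"), prefix="A")
    d2 = TaxonomyDefaults(parse_taxonomy_id("CCN202001011"), prefix="B")
    registry = Registry()
    t1 = build_taxonomy(d1, caterpillar_tree(["x", "y"]))
    t2 = build_taxonomy(d2, caterpillar_tree(["p", "q"]))
    registry.add(t1)
    registry.add(t2)
    cells = ["c1", "c2", "c3"]
    m1 = pd.DataFrame({"CS202001010_1": [1, 1, 0], "CS202001010_2": [0, 0, 1]}, index=cells)
    m2 = pd.DataFrame({"CS202001011_1": [1, 1, 0], "CS202001011_2": [0, 0, 1]}, index=cells)
    graph = build_link_graph(registry, cell_memberships={"CCN202001010": m1, "CCN202001011": m2})
    assert graph.get_edge_data(("CCN202001010", "CS202001010_1"), ("CCN202001011", "CS202001011_1"))["kind"] == "co_cell"


def test_transfer_aligned_aliases_with_provenance():
    source = build_taxonomy(TaxonomyDefaults(parse_taxonomy_id("CCN202001010"), prefix="REF"),
                            caterpillar_tree(["r1", "r2"]))
    src_edits = {cs.accession.render(): alias for cs, alias in zip(source.leaves(), ["L5 ET 1", "Pvalb 2"])}
    source = source.with_cell_sets([
        type(cs)(**{**cs.__dict__, "aliases": cs.aliases + ((Alias(src_edits[cs.accession.render()], "aligned"),)
                                                            if cs.accession.render() in src_edits else ())})
        for cs in source.cell_sets
    ])
    target = build_taxonomy(TaxonomyDefaults(parse_taxonomy_id("CCN202001011"), prefix="TGT"),
                            caterpillar_tree(["t1", "t2"]))
    mapping = {"CS202001011_1": "CS202001010_1", "CS202001011_2": "CS202001010_2"}
    once = transfer_aligned_aliases(source, target, mapping)
    assert once.get("CS202001011_1").aligned_alias == "L5 ET 1"
    assert once.get("CS202001011_1").alias("aligned").citation == "CCN202001010"
    assert transfer_aligned_aliases(source, once, mapping) == once
    assert transfer_aligned_aliases(source, target, {}) == target
    with pytest.raises(RegistryError, match="unknown accessions"):
        transfer_aligned_aliases(source, target, {"CS202001011_9": "CS202001010_1"})
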