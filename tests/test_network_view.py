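import pytest

from pathwayviews.fixtures import FixtureSpec, make_fixture
from pathwayviews.model import (
    DataNode,
    GraphicsProps,
    Group,
    Interaction,
    Label,
    PathwayDocument,
    Point,
    Shape,
    Xref,
)
from pathwayviews.network_view import (
    NetworkOptions,
    apply_layout,
    merge_key,
    merge_report,
    to_network_view,
)
from conftest import fixture_specs


def example_doc():
    """The enumeration example: 5 DataNodes (2 sharing an Xref), 1 Label,
    1 Shape, 1 Group of 2, 3 Interactions, no anchors."""
    dns = [
        DataNode(f"d{i}", f"G{i}", "GeneProduct", Xref("Entrez Gene", xid),
                 graphics=GraphicsProps(center_x=10.0 * i, center_y=0.0))
        for i, xid in enumerate(["1", "1", "2", "3", "4"])
    ]
    dns[3].group_ref = "grp"
    dns[4].group_ref = "grp"
    return PathwayDocument(
        data_nodes=dns,
        labels=[Label("lab", "text")],
        shapes=[Shape("shp")],
        groups=[Group("grp")],
        interactions=[
            Interaction("i1", points=[Point(graph_ref="d0"), Point(graph_ref="d2", arrow_head="Arrow")]),
            Interaction("i2", points=[Point(graph_ref="d2"), Point(graph_ref="d3", arrow_head="Arrow")]),
            Interaction("i3", points=[Point(graph_ref="d3"), Point(graph_ref="d4", arrow_head="TBar")]),
        ],
    )


class TestMergeKey:
    def test_complete_xref_wins(self):
        dn = DataNode("n", "CDK2", "GeneProduct", Xref("Entrez Gene", "1017"))
        key = merge_key(dn)
        assert (key.kind, key.first, key.second) == ("xref", "Entrez Gene", "1017")

    def test_same_xref_different_ids_merge(self):
        a = DataNode("a", "CDK2", "GeneProduct", Xref("Entrez Gene", "1017"))
        b = DataNode("b", "cdk-2 copy", "GeneProduct", Xref("Entrez Gene", "1017"))
        assert merge_key(a) == merge_key(b)

    def test_label_fallback_for_empty_xref(self):
        dn = DataNode("n", "ATP", "Metabolite", Xref())
        key = merge_key(dn)
        assert (key.kind, key.first, key.second) == ("label", "Metabolite", "ATP")

    def test_partial_xref_falls_back_to_label(self):
        dn = DataNode("n", "ATP", "Metabolite", Xref("ChEBI", ""))
        assert merge_key(dn).kind == "label"


class TestNetworkConversion:
    def test_example_enumeration(self):
        graph, styles = to_network_view(example_doc())
        molecules = graph.nodes_of_kind("molecule")
        assert len(molecules) == 4  # d0/d1 merged
        assert len(graph.nodes_of_kind("group")) == 1
        assert len(graph.nodes_of_kind("annotation")) == 0
        assert "lab" not in graph.nodes and "shp" not in graph.nodes
        assert len(graph.nodes) == 5
        itypes = sorted(e.interaction_type for e in graph.edges.values())
        assert itypes == ["Arrow", "Arrow", "TBar", "contains", "contains"]
        assert len(graph.edges) == 5

    def test_merged_node_records_sources_and_representative(self):
        graph, _ = to_network_view(example_doc())
        merged = graph.nodes["d0"]
        assert merged.attributes["merged_ids"] == "d0;d1"
        assert merged.attributes["label"] == "G0"  # first in document order

    def test_distinct_xrefs_mean_no_merging(self):
        doc = make_fixture(FixtureSpec(n_datanodes=6, seed=3))
        graph, _ = to_network_view(doc)
        assert len(graph.nodes_of_kind("molecule")) == 6

    def test_group_and_connector_nodes_are_very_small(self, canonical_doc):
        graph, styles = to_network_view(canonical_doc)
        for node in [*graph.nodes_of_kind("group"), *graph.nodes_of_kind("connector")]:
            assert styles.get(node.node_id, "width") == 5.0
            assert styles.get(node.node_id, "height") == 5.0

    def test_anchor_splits_interaction_in_network_view(self, canonical_doc):
        graph, _ = to_network_view(canonical_doc)
        assert graph.nodes["anch0"].kind == "connector"
        segs = [e for e in graph.edges.values() if e.attributes.get("parent_line") == "ia0"]
        assert len(segs) == 2
        assert all("anch0" in (e.source, e.target) for e in segs)

    def test_dangling_endpoint_dropped_with_default_options(self):
        doc = example_doc()
        doc.interactions.append(
            Interaction("loose", points=[Point(graph_ref="d0"), Point(x=5.0, y=5.0)])
        )
        graph, _ = to_network_view(doc)
        assert not any(e.attributes.get("parent_line") == "loose" for e in graph.edges.values())
        assert graph.meta["dropped_dangling_edges"] == 1

    def test_parallel_edges_collapse_with_multiplicity(self):
        doc = example_doc()
        doc.interactions.append(
            Interaction("i1b", points=[Point(graph_ref="d0"), Point(graph_ref="d2", arrow_head="Arrow")])
        )
        graph, _ = to_network_view(doc)
        hits = [
            e for e in graph.edges.values()
            if {e.source, e.target} == {"d0", "d2"} and e.interaction_type == "Arrow"
        ]
        assert len(hits) == 1
        assert hits[0].attributes["multiplicity"] == 2

    def test_annotation_free_invariant_over_sweep(self):
        for spec in fixture_specs(15):
            graph, _ = to_network_view(make_fixture(spec))
            assert graph.nodes_of_kind("annotation") == []
            assert not any(e.attributes.get("graphical") for e in graph.edges.values())

    def test_full_conversion_is_deterministic(self, canonical_doc):
        from pathwayviews.export import to_json_graph

        a = to_network_view(canonical_doc)
        b = to_network_view(canonical_doc)
        assert to_json_graph(*a) == to_json_graph(*b)
        assert a[1].to_tsv() == b[1].to_tsv()


class TestMergeReport:
    def test_partition_property_over_sweep(self):
        for spec in fixture_specs(15):
            doc = make_fixture(spec)
            report = merge_report(doc)
            all_ids = [gid for gids in report.values() for gid in gids]
            assert sorted(all_ids) == sorted(dn.graph_id for dn in doc.data_nodes)
            assert len(all_ids) == len(set(all_ids))
            pairs = sum(1 for gids in report.values() if len(gids) == 2)
            assert pairs == spec.n_redundant_pairs

    def test_example_report_shape(self):
        report = merge_report(example_doc())
        sizes = sorted(len(v) for v in report.values())
        assert sizes == [1, 1, 1, 2]

    def test_empty_document(self):
        assert merge_report(PathwayDocument()) == {}

    def test_keys_are_image_of_merge_key(self, canonical_doc):
        report = merge_report(canonical_doc)
        assert set(report) == {merge_key(dn) for dn in canonical_doc.data_nodes}


class TestLayout:
    def test_same_seed_identical_coordinates(self, canonical_doc):
        graph, _ = to_network_view(canonical_doc)
        a = apply_layout(graph, seed=42, iterations=50)
        b = apply_layout(graph, seed=42, iterations=50)
        assert a == b  # exact, not approximate

    def test_coordinates_finite_and_distinct(self, canonical_doc):
        import math

        graph, _ = to_network_view(canonical_doc)
        coords = apply_layout(graph, seed=1, iterations=50)
        assert len(coords) == len(graph.nodes)
        assert all(math.isfinite(x) and math.isfinite(y) for x, y in coords.values())
        assert len(set(coords.values())) == len(coords)

    def test_single_node_at_origin(self):
        from pathwayviews.graph import NetworkGraph

        g = NetworkGraph()
        g.add_node("only", "molecule")
        assert apply_layout(g) == {"only": (0.0, 0.0)}

    def test_two_connected_nodes_within_separation_bounds(self):
        import math

        from pathwayviews.graph import NetworkGraph

        g = NetworkGraph()
        g.add_node("a", "molecule")
        g.add_node("b", "molecule")
        g.add_edge("e", "a", "b")
        coords = apply_layout(g, seed=5, iterations=100)
        d = math.dist(coords["a"], coords["b"])
        assert 1e-3 <= d <= 10.0  # ideal edge length is O(1) on the unit scale

    def test_empty_graph_is_an_error(self):
        from pathwayviews.graph import NetworkGraph

        with pytest.raises(ValueError):
            apply_layout(NetworkGraph())

    def test_iterations_must_be_positive(self):
        with pytest.raises(ValueError):
            NetworkOptions(layout_iterations=0)
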