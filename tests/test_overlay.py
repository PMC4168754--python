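import io
import math

import pytest

from pathwayviews.fixtures import canonical_fixture, make_demo_data
from pathwayviews.graph import NetworkGraph
from pathwayviews.network_view import to_network_view
from pathwayviews.overlay import (
    DataJoinError,
    VisualMapping,
    apply_data_styles,
    centrality_styles,
    gradient_color,
    join_data,
    map_identifiers,
    read_data_table,
    read_mapping_table,
)


@pytest.fixture
def overlaid_graph(canonical_doc, demo_data_path, demo_mapping_path):
    graph, _ = to_network_view(canonical_doc)
    map_identifiers(graph, read_mapping_table(demo_mapping_path))
    join_data(graph, read_data_table(demo_data_path))
    return graph


class TestGradient:
    VM = VisualMapping(domain_limit=2.0)

    def test_midpoint_is_white(self):
        assert gradient_color(0.0, self.VM) == "FFFFFF"

    def test_endpoints(self):
        assert gradient_color(2.0, self.VM) == "FF0000"
        assert gradient_color(-2.0, self.VM) == "0000FF"

    def test_half_scale_linear_interpolation(self):
        assert gradient_color(1.0, self.VM) == "FF8080"
        assert gradient_color(-1.0, self.VM) == "8080FF"

    def test_clamping_beyond_domain(self):
        assert gradient_color(99.0, self.VM) == "FF0000"
        assert gradient_color(-99.0, self.VM) == "0000FF"

    def test_symmetry_of_default_palette(self):
        # color(-x) is the blue mirror of color(+x): R and B channels swap
        for x in (0.3, 0.77, 1.5, 2.0):
            pos = gradient_color(x, self.VM)
            neg = gradient_color(-x, self.VM)
            assert neg == pos[4:6] + pos[2:4] + pos[0:2]

    def test_continuity_near_zero(self):
        assert gradient_color(1e-12, self.VM) == "FFFFFF"

    def test_non_finite_treated_as_missing(self):
        assert gradient_color(float("nan"), self.VM) is None
        assert gradient_color(float("inf"), self.VM) is None


class TestIdentifierMapping:
    def test_direct_lookup(self):
        g = NetworkGraph()
        g.add_node("n", "molecule", xref_identifier="1017")
        map_identifiers(g, {"1017": ["ENSG00000123374"]})
        assert g.nodes["n"].attributes["mapped_id"] == "ENSG00000123374"

    def test_missing_entry_flagged_unmapped(self):
        g = NetworkGraph()
        g.add_node("n", "molecule", xref_identifier="999")
        map_identifiers(g, {"1017": ["ENSG1"]})
        assert g.nodes["n"].attributes["unmapped"] is True
        assert "mapped_id" not in g.nodes["n"].attributes

    def test_one_to_many_takes_first_and_counts_ambiguity(self):
        g = NetworkGraph()
        g.add_node("n", "molecule", xref_identifier="1017")
        map_identifiers(g, {"1017": ["A", "B"]})
        assert g.nodes["n"].attributes["mapped_id"] == "A"
        assert g.meta["mapping_report"]["ambiguous"] == 1

    def test_empty_mapping_leaves_all_unmapped(self):
        g = NetworkGraph()
        g.add_node("n", "molecule", xref_identifier="1")
        map_identifiers(g, {})
        assert g.meta["mapping_report"]["unmapped"] == 1

    def test_mapping_table_reader_dedups_preserving_order(self):
        table = read_mapping_table(io.StringIO("# comment\n1017\tA\n1017\tB\n1017\tA\n"))
        assert table == {"1017": ["A", "B"]}


class TestJoin:
    def test_measured_node_gets_attributes(self, overlaid_graph):
        measured = [
            n for n in overlaid_graph.nodes_of_kind("molecule") if "logFC" in n.attributes
        ]
        assert len(measured) == overlaid_graph.meta["measured_count"] == 3
        for n in measured:
            assert 0.0 <= n.attributes["adj_p_value"] <= 1.0

    def test_unmatched_node_keeps_no_data(self, overlaid_graph):
        unmeasured = [
            n for n in overlaid_graph.nodes_of_kind("molecule") if "logFC" not in n.attributes
        ]
        assert len(unmeasured) == 1
        assert "p_value" not in unmeasured[0].attributes

    def test_duplicate_key_is_an_error(self):
        g = NetworkGraph()
        g.add_node("n", "molecule", mapped_id="X")
        df = read_data_table(io.StringIO("id\tlogFC\nX\t1.0\nX\t2.0\n"))
        with pytest.raises(DataJoinError, match="X"):
            join_data(g, df)

    def test_join_is_idempotent(self, overlaid_graph, demo_data_path):
        before = {n.node_id: dict(n.attributes) for n in overlaid_graph.nodes.values()}
        join_data(overlaid_graph, read_data_table(demo_data_path))
        after = {n.node_id: dict(n.attributes) for n in overlaid_graph.nodes.values()}
        assert before == after

    def test_out_of_range_pvalues_rejected_at_read(self, caplog):
        df = read_data_table(io.StringIO("id\tlogFC\tp_value\tadj_p_value\nA\t1\t0.5\t0.6\nB\t1\t1.5\t0.6\n"))
        assert list(df.index) == ["A"]


class TestDataStyles:
    def test_significant_upregulated_node(self):
        g = NetworkGraph()
        g.add_node("n", "molecule", logFC=2.0, adj_p_value=0.01)
        styles = apply_data_styles(g, VisualMapping(domain_limit=2.0))
        assert styles.get("n", "fill_color") == "FF0000"
        assert styles.get("n", "border_color") == "00FF00"

    def test_unmeasured_node_is_grey_with_default_border(self):
        g = NetworkGraph()
        g.add_node("n", "molecule")
        styles = apply_data_styles(g, VisualMapping(domain_limit=1.0))
        assert styles.get("n", "fill_color") == "C8C8C8"
        assert styles.get("n", "border_color") == "000000"

    def test_alpha_boundary_is_strict(self):
        g = NetworkGraph()
        g.add_node("n", "molecule", logFC=1.0, adj_p_value=0.05)
        styles = apply_data_styles(g, VisualMapping(domain_limit=1.0))
        assert styles.get("n", "border_color") == "000000"

    def test_partition_measured_or_missing(self, overlaid_graph):
        styles = apply_data_styles(overlaid_graph)
        molecules = overlaid_graph.nodes_of_kind("molecule")
        grey = [n for n in molecules if styles.get(n.node_id, "fill_color") == "C8C8C8"]
        colored = [n for n in molecules if styles.get(n.node_id, "fill_color") != "C8C8C8"]
        assert len(grey) + len(colored) == len(molecules)
        assert len(colored) == overlaid_graph.meta["measured_count"]

    def test_non_molecule_nodes_untouched(self, overlaid_graph):
        styles = apply_data_styles(overlaid_graph)
        for node in overlaid_graph.nodes_of_kind("group"):
            assert styles.get(node.node_id, "fill_color") is None

    def test_default_domain_limit_is_max_abs_logfc(self, overlaid_graph):
        styles = apply_data_styles(overlaid_graph)
        fcs = [
            n.attributes["logFC"]
            for n in overlaid_graph.nodes_of_kind("molecule")
            if "logFC" in n.attributes
        ]
        extreme = max(fcs, key=abs)
        node = next(
            n for n in overlaid_graph.nodes_of_kind("molecule")
            if n.attributes.get("logFC") == extreme
        )
        expected = "FF0000" if extreme > 0 else "0000FF"
        assert styles.get(node.node_id, "fill_color") == expected

    def test_apply_is_deterministic_and_idempotent(self, overlaid_graph):
        a = apply_data_styles(overlaid_graph)
        b = apply_data_styles(overlaid_graph)
        assert a.to_tsv() == b.to_tsv()


class TestCentralityStyles:
    def make_path_graph(self):
        g = NetworkGraph()
        for n in "abc":
            g.add_node(n, "molecule")
        g.add_edge("e1", "a", "b")
        g.add_edge("e2", "b", "c")
        return g

    def test_size_range_endpoints_and_monotonicity(self):
        from pathwayviews.topology import betweenness, degree

        g = self.make_path_graph()
        deg, btw = degree(g), betweenness(g)
        styles = centrality_styles(g, deg, btw)
        assert styles.get("b", "size") == 80.0
        assert styles.get("a", "size") == 20.0
        sizes = {n: styles.get(n, "size") for n in g.nodes}
        for x in g.nodes:
            for y in g.nodes:
                if deg[x] < deg[y]:
                    assert sizes[x] <= sizes[y]

    def test_max_betweenness_gets_high_color(self):
        from pathwayviews.topology import betweenness, degree

        g = self.make_path_graph()
        styles = centrality_styles(g, degree(g), betweenness(g))
        assert styles.get("b", "fill_color") == "FF0000"
        assert styles.get("a", "fill_color") == "0000FF"

    def test_constant_metric_maps_to_mid_range(self):
        g = NetworkGraph()
        g.add_node("a", "molecule")
        g.add_node("b", "molecule")
        g.add_edge("e", "a", "b")
        styles = centrality_styles(g, {"a": 1, "b": 1}, {"a": 0.0, "b": 0.0})
        assert styles.get("a", "size") == 50.0
        assert styles.get("a", "fill_color") == "FFFFFF"


def test_visual_mapping_validates_parameters():
    with pytest.raises(ValueError):
        VisualMapping(domain_limit=0.0)
    with pytest.raises(ValueError):
        VisualMapping(alpha=1.0)
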