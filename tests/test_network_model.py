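import itertools

import pytest

from netkd import (
    DEFAULT_WEIGHT_SCHEME,
    EdgeKind,
    PathwayNetwork,
    WeightScheme,
    add_self_inhibition,
    assign_weights,
    merge_networks,
    parse_kgml,
    read_network,
    write_network,
)
from netkd.network_model import KGMLParseError, NetworkMergeError


def kgml(entries: str, relations: str = "") -> str:
    return f'<pathway name="hsa00000">{entries}{relations}</pathway>'


def gene_entry(eid: str, symbols: str, kegg: str = "") -> str:
    return (f'<entry id="{eid}" name="{kegg or "hsa:" + eid}" type="gene">'
            f'<graphics name="{symbols}"/></entry>')


def relation(e1: str, e2: str, subtype: str | None = "activation") -> str:
    sub = f'<subtype name="{subtype}" value="--&gt;"/>' if subtype else ""
    return f'<relation entry1="{e1}" entry2="{e2}" type="PPrel">{sub}</relation>'


class TestParseKGML:
    def test_minimal_two_genes_one_activation(self):
        doc = kgml(gene_entry("1", "INS") + gene_entry("2", "INSR"),
                   relation("1", "2"))
        net = parse_kgml(doc)
        assert net.node_ids == ["INS", "INSR"]
        (edge,) = net.edges
        assert (edge.source, edge.target, edge.kind) == \
            ("INS", "INSR", EdgeKind.ACTIVATION)

    def test_multi_gene_entry_expands_and_duplicates_relations(self):
        doc = kgml(
            gene_entry("1", "AKT1, AKT2, AKT3", "hsa:207 hsa:208 hsa:10000")
            + gene_entry("2", "HRAS"),
            relation("2", "1"))
        net = parse_kgml(doc)
        assert net.node_ids == ["AKT1", "AKT2", "AKT3", "HRAS"]
        edges = net.edges
        assert len(edges) == 3
        assert {e.target for e in edges} == {"AKT1", "AKT2", "AKT3"}
        assert all(e.kind is EdgeKind.ACTIVATION and e.source == "HRAS"
                   for e in edges)

    def test_unmapped_subtype_becomes_unknown_weight_zero(self):
        doc = kgml(gene_entry("1", "A") + gene_entry("2", "B"),
                   relation("1", "2", "state change"))
        (edge,) = parse_kgml(doc).edges
        assert edge.kind is EdgeKind.UNKNOWN
        assert edge.weight == 0

    def test_group_entry_becomes_complex_node(self):
        doc = kgml(
            gene_entry("1", "PIK3CA") + gene_entry("2", "PIK3R1")
            + '<entry id="3" name="undefined" type="group">'
              '<component id="1"/><component id="2"/></entry>'
            + gene_entry("4", "HRAS"),
            relation("4", "3", "binding/association"))
        net = parse_kgml(doc)
        complex_nodes = [n for n in net.nodes if n.kind == "complex"]
        assert len(complex_nodes) == 1
        assert complex_nodes[0].id == "PIK3CA+PIK3R1"
        (edge,) = net.edges
        assert edge.kind is EdgeKind.BINDING_ASSOCIATION
        assert edge.weight == 2

    def test_compound_entry_kind(self):
        doc = kgml('<entry id="1" name="cpd:C00165" type="compound">'
                   '<graphics name="diacylglycerol"/></entry>')
        (node,) = parse_kgml(doc).nodes
        assert node.kind == "compound"
        assert node.id == "diacylglycerol"

    def test_entry_without_name_falls_back_to_entry_id(self, caplog):
        doc = kgml('<entry id="42" name="" type="gene"><graphics/></entry>')
        with caplog.at_level("WARNING"):
            net = parse_kgml(doc)
        assert net.node_ids == ["entry42"]
        assert "42" in caplog.text

    def test_malformed_xml_raises_parse_error(self):
        with pytest.raises(KGMLParseError, match="malformed"):
            parse_kgml("<pathway><entry id='1'")

    def test_relation_to_unknown_entry_names_it(self):
        doc = kgml(gene_entry("1", "A"), relation("1", "99"))
        with pytest.raises(KGMLParseError, match="99"):
            parse_kgml(doc)


class TestMerge:
    def net_ab(self, a, b, kind=EdgeKind.ACTIVATION, name="p1"):
        net = PathwayNetwork(name)
        net.add_edge(a, b, kind, provenance=[name])
        return net

    def test_disjoint_union(self):
        merged = merge_networks([self.net_ab("A", "B"), self.net_ab("C", "D")])
        assert merged.node_ids == ["A", "B", "C", "D"]
        assert len(merged.edges) == 2

    def test_duplicate_edge_collapses_with_provenance_union(self):
        merged = merge_networks([self.net_ab("X", "AKT3", name="p1"),
                                 self.net_ab("X", "AKT3", name="p2")])
        (edge,) = merged.edges
        assert edge.provenance == frozenset({"p1", "p2"})

    def test_conflicting_kinds_both_retained(self):
        merged = merge_networks([
            self.net_ab("A", "B", EdgeKind.ACTIVATION),
            self.net_ab("A", "B", EdgeKind.INHIBITION, name="p2")])
        kinds = {e.kind for e in merged.edges}
        assert kinds == {EdgeKind.ACTIVATION, EdgeKind.INHIBITION}
        assert len(merged.edges) == 2

    def test_gene_compound_id_collision_is_an_error(self):
        gene = PathwayNetwork("p1")
        gene.add_node("ATP", kind="gene")
        compound = PathwayNetwork("p2")
        compound.add_node("ATP", kind="compound")
        with pytest.raises(NetworkMergeError, match="ATP"):
            merge_networks([gene, compound])

    def test_merge_order_insensitive(self):
        parts = [self.net_ab("A", "B"),
                 self.net_ab("B", "C", EdgeKind.INHIBITION, name="p2"),
                 self.net_ab("A", "C", EdgeKind.PHOSPHORYLATION, name="p3")]
        reference = merge_networks(parts)
        for perm in itertools.permutations(parts):
            assert merge_networks(list(perm)) == reference


class TestSelfInhibitionAndWeights:
    def test_every_node_gains_one_self_loop(self):
        net = PathwayNetwork("n")
        for g in "ABC":
            net.add_node(g)
        out = add_self_inhibition(net)
        loops = [e for e in out.edges if e.source == e.target]
        assert len(loops) == 3
        assert all(e.kind is EdgeKind.SELF_INHIBITION and e.weight == -1
                   for e in loops)

    def test_idempotent(self):
        net = PathwayNetwork("n")
        net.add_edge("A", "B", EdgeKind.ACTIVATION)
        once = add_self_inhibition(net)
        assert add_self_inhibition(once) == once

    def test_compounds_and_complexes_also_decay(self):
        net = PathwayNetwork("n")
        net.add_node("G1")
        net.add_node("G2")
        net.add_node("dag", kind="compound")
        out = add_self_inhibition(net)
        assert sum(e.source == e.target for e in out.edges) == 3

    @pytest.mark.parametrize("kind,weight", [
        (EdgeKind.PHOSPHORYLATION, 2),
        (EdgeKind.UBIQUITINATION, -1),
        (EdgeKind.UNKNOWN, 0),
        (EdgeKind.BINDING_ASSOCIATION, 2),
        (EdgeKind.DISSOCIATION, -1),
    ])
    def test_default_scheme_weights(self, kind, weight):
        net = PathwayNetwork("n")
        net.add_edge("A", "B", kind, weight=99)
        (edge,) = assign_weights(net).edges
        assert edge.weight == weight

    def test_default_weights_are_in_expected_range(self):
        assert set(DEFAULT_WEIGHT_SCHEME.kind_to_weight.values()) <= {-1, 0, 2}

    def test_missing_kind_in_scheme_names_it(self):
        net = PathwayNetwork("n")
        net.add_edge("A", "B", EdgeKind.DISSOCIATION)
        with pytest.raises(KeyError, match="dissociation"):
            assign_weights(net, WeightScheme({EdgeKind.ACTIVATION: 2}))


class TestSerialization:
    def build_sample(self):
        net = PathwayNetwork("sample")
        net.add_node("dag", kind="compound")
        net.add_edge("INS", "INSR", EdgeKind.ACTIVATION, weight=2,
                     provenance=["p1"])
        net.add_edge("INSR", "dag", EdgeKind.INHIBITION, weight=-1,
                     provenance=["p1", "p2"])
        return add_self_inhibition(net)

    def test_graphml_round_trip_is_identity(self, tmp_path):
        net = self.build_sample()
        path = tmp_path / "net.graphml"
        write_network(net, str(path), "graphml")
        back = read_network(str(path))
        assert back == net
        # full fidelity: kinds and provenance survive too
        assert {(n.id, n.kind) for n in back.nodes} == \
            {(n.id, n.kind) for n in net.nodes}
        assert {(e.source, e.target, e.kind, e.provenance)
                for e in back.edges} == \
            {(e.source, e.target, e.kind, e.provenance) for e in net.edges}

    def test_sif_round_trip_preserves_default_weighted_edges(self, tmp_path):
        net = PathwayNetwork("n")
        net.add_edge("INS", "INSR", EdgeKind.ACTIVATION)
        net.add_edge("A", "B", EdgeKind.INHIBITION)
        path = tmp_path / "net.sif"
        write_network(net, str(path), "sif")
        assert read_network(str(path)) == net

    def test_sif_line_parses_to_activation_edge(self, tmp_path):
        path = tmp_path / "mini.sif"
        path.write_text("INS\tactivation\tINSR\n")
        (edge,) = read_network(str(path)).edges
        assert (edge.source, edge.kind, edge.target, edge.weight) == \
            ("INS", EdgeKind.ACTIVATION, "INSR", 2)

    def test_graphml_self_loop_weight_minus_one_is_self_inhibition(
            self, tmp_path):
        net = add_self_inhibition(PathwayNetwork("n"))
        net.add_node("G")
        net = add_self_inhibition(net)
        path = tmp_path / "loop.graphml"
        write_network(net, str(path), "graphml")
        (edge,) = read_network(str(path)).edges
        assert edge.kind is EdgeKind.SELF_INHIBITION
        assert edge.weight == -1
        assert edge.source == edge.target == "G"

    def test_unknown_format_rejected(self, tmp_path):
        net = PathwayNetwork("n")
        with pytest.raises(ValueError, match="format"):
            write_network(net, str(tmp_path / "x"), "xlsx")
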