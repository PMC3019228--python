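"""Path queries, common regulators/targets, attribute search, overlays, SIF."""

import itertools

import numpy as np
import pytest

from bionetkit.enrichment import hypergeom_tail
from bionetkit.expression import CoexpressionResult
from bionetkit.netquery import (
    InteractionRecord,
    Network,
    attribute_search,
    common_regulators,
    common_targets,
    connect_to_pathways,
    find_paths,
    overlay,
    parse_condition,
    read_sif,
    write_sif,
)


def edge(s, t, rel="other", directed=False, **kw):
    return InteractionRecord(s, t, rel, directed, **kw)


@pytest.fixture
def chain_net():
    return Network([
        edge("a", "b", "tf_dna", directed=True),
        edge("b", "c", "tf_dna", directed=True),
    ])


class TestFindPaths:
    def test_chain_found_at_sufficient_length(self, chain_net):
        res = find_paths(chain_net, {"a"}, {"c"}, max_len=2)
        assert res.paths == [("a", "b", "c")]

    def test_too_short_max_len_finds_nothing(self, chain_net):
        assert find_paths(chain_net, {"a"}, {"c"}, max_len=1).paths == []

    def test_direction_respected_and_relaxed(self, chain_net):
        assert find_paths(chain_net, {"c"}, {"a"}, 2, "directed").paths == []
        assert find_paths(chain_net, {"c"}, {"a"}, 2, "either").paths == \
            [("c", "b", "a")]

    def test_undirected_symmetric_in_sources_targets(self):
        rng = np.random.default_rng(4)
        edges = [edge(f"n{i}", f"n{int(rng.integers(8))}", directed=True)
                 for i in range(8) if f"n{i}" != f"n{int(rng.integers(8))}"]
        edges = [e for e in edges if e.source_id != e.target_id]
        net = Network(edges)
        fwd = find_paths(net, {"n0"}, {"n5"}, 4, "undirected").paths
        rev = find_paths(net, {"n5"}, {"n0"}, 4, "undirected").paths
        assert sorted(tuple(reversed(p)) for p in fwd) == sorted(rev)

    def test_edge_filter_applies(self, chain_net):
        res = find_paths(chain_net, {"a"}, {"c"}, 3,
                         edge_filter=lambda e: e.relation_type == "ppi")
        assert res.paths == []

    def test_missing_sources_warn_and_empty(self, chain_net):
        with pytest.warns(UserWarning, match="no query source"):
            assert find_paths(chain_net, {"zz"}, {"c"}, 2).paths == []

    def test_truncation_flag(self):
        # complete graph on 8 nodes explodes combinatorially
        nodes = [f"n{i}" for i in range(8)]
        net = Network([edge(a, b, directed=True)
                       for a, b in itertools.permutations(nodes, 2)])
        res = find_paths(net, {"n0"}, {"n7"}, 6, max_paths=50)
        assert res.truncated and len(res.paths) <= 50

    def test_equals_brute_force_dfs(self):
        rng = np.random.default_rng(23)
        nodes = [f"n{i}" for i in range(12)]
        edges = []
        for a, b in itertools.combinations(nodes, 2):
            if rng.random() < 0.25:
                edges.append(edge(a, b, directed=bool(rng.random() < 0.6)))
        net = Network(edges)

        # oracle: exhaustive DFS over the same traversal relation
        adj = {n: set() for n in nodes}
        for e in edges:
            adj[e.source_id].add(e.target_id)
            if not e.directed:
                adj[e.target_id].add(e.source_id)

        def dfs_all(src, dst, max_len):
            out = set()
            stack = [(src, (src,))]
            while stack:
                cur, path = stack.pop()
                if cur == dst and len(path) > 1:
                    out.add(path)
                    continue
                if len(path) > max_len:
                    continue
                for nxt in adj[cur]:
                    if nxt not in path:
                        stack.append((nxt, path + (nxt,)))
            return {p for p in out if len(p) - 1 <= max_len}

        for src, dst, k in (("n0", "n11", 3), ("n1", "n5", 4), ("n2", "n9", 5)):
            got = set(find_paths(net, {src}, {dst}, k, "directed").paths)
            assert got == dfs_all(src, dst, k), (src, dst, k)


class TestCommonRegulatorsTargets:
    def test_regulators_intersection(self):
        net = Network([
            edge("T1", "g1", "tf_dna", True), edge("T1", "g2", "tf_dna", True),
            edge("T2", "g1", "tf_dna", True), edge("T2", "g2", "tf_dna", True),
            edge("T3", "g1", "tf_dna", True),
        ])
        assert common_regulators(net, {"g1", "g2"}) == {"T1", "T2"}
        assert common_regulators(net, {"g1"}) == {"T1", "T2", "T3"}
        assert common_targets(net, {"T1", "T2"}) == {"g1", "g2"}

    def test_undirected_edges_do_not_regulate(self):
        net = Network([edge("p", "g1", "ppi", directed=False)])
        assert common_regulators(net, {"g1"}) == set()

    def test_union_rule(self):
        rng = np.random.default_rng(6)
        edges = [edge(f"T{i}", f"g{j}", "tf_dna", True)
                 for i in range(4) for j in range(5) if rng.random() < 0.5]
        net = Network(edges)
        s1, s2 = {"g0", "g1"}, {"g2"}
        assert common_regulators(net, s1 | s2) == \
            common_regulators(net, s1) & common_regulators(net, s2)

    def test_empty_node_set_raises(self):
        with pytest.raises(ValueError):
            common_regulators(Network(), set())


class TestConnectToPathways:
    def test_exact_pathway_match_first(self):
        collection = {"P1": {"a", "b", "c"}, "P2": {"c", "d", "e", "f"}}
        res = connect_to_pathways({"a", "b", "c"}, collection)
        assert res[0]["pathway"] == "P1"
        assert res[0]["k"] == res[0]["M"] == 3

    def test_disjoint_set_empty(self):
        assert connect_to_pathways({"x"}, {"P": {"a", "b"}}) == []

    def test_p_matches_enrichment_module(self):
        collection = {"P": {"a", "b", "c", "d"}}
        background = {f"g{i}" for i in range(20)} | collection["P"] | {"q"}
        res = connect_to_pathways({"a", "b", "q"}, collection, background)
        assert res[0]["p"] == pytest.approx(
            hypergeom_tail(2, 3, 4, len(background)))


class TestAttributeSearch:
    @pytest.fixture
    def net(self):
        rng = np.random.default_rng(31)
        edges = []
        for i in range(100):
            edges.append(InteractionRecord(
                f"s{i}", f"t{i}",
                relation_type=("tf_dna", "ppi", "coexpression")[i % 3],
                directed=bool(i % 2),
                effect=("positive", "negative", "unknown")[i % 3],
                p_value=float(rng.uniform(1e-6, 1)),
                attributes={"score": float(rng.uniform(0, 10))},
            ))
        return Network(edges)

    def test_conjunction(self, net):
        got = attribute_search(
            net, {"and": [{"field": "relation_type", "op": "=", "value": "tf_dna"},
                          {"field": "p_value", "op": "<", "value": 1e-1}]})
        assert got == [e for e in net.edges
                       if e.relation_type == "tf_dna" and e.p_value < 1e-1]

    def test_negation(self, net):
        got = attribute_search(
            net, {"not": {"field": "effect", "op": "=", "value": "negative"}})
        assert {e.effect for e in got} <= {"positive", "unknown"}
        assert len(got) == sum(e.effect != "negative" for e in net.edges)

    def test_nested_matches_truth_table(self, net):
        cond = {"and": [
            {"or": [{"field": "relation_type", "op": "=", "value": "ppi"},
                    {"field": "score", "op": ">=", "value": 5.0}]},
            {"field": "p_value", "op": "<=", "value": 0.5},
        ]}
        got = set(map(id, attribute_search(net, cond)))
        for e in net.edges:
            a = e.relation_type == "ppi"
            b = e.attributes["score"] >= 5.0
            c = e.p_value <= 0.5
            assert ((a or b) and c) == (id(e) in got)

    def test_infix_string_equivalent_to_tree(self, net):
        text = "(relation_type = tf_dna) AND (p_value < 1e-1)"
        assert attribute_search(net, text) == attribute_search(
            net, {"and": [{"field": "relation_type", "op": "=", "value": "tf_dna"},
                          {"field": "p_value", "op": "<", "value": "1e-1"}]})

    def test_unknown_field_raises(self, net):
        with pytest.raises(KeyError, match="no_such"):
            attribute_search(net, {"field": "no_such", "op": "=", "value": 1})

    def test_type_mismatch_raises(self, net):
        with pytest.raises(TypeError):
            attribute_search(net, {"field": "effect", "op": "<", "value": 3})

    def test_node_search_with_glob(self):
        net = Network()
        net.add_node("CREB1", kind="TF")
        net.add_node("GATA1", kind="TF")
        net.add_node("ACTB", kind="gene")
        got = attribute_search(
            net, {"and": [{"field": "kind", "op": "=", "value": "TF"},
                          {"field": "id", "op": "matches", "value": "g*"}]},
            over="nodes")
        assert got == ["GATA1"]

    def test_parse_condition_rejects_malformed(self):
        with pytest.raises(ValueError):
            parse_condition("(a = 1")
        with pytest.raises(ValueError):
            parse_condition("a =")


class TestOverlay:
    def test_coexpression_support_becomes_edge_attribute(self, chain_net):
        res = CoexpressionResult(("a", "b"), [f"e{i}" for i in range(12)])
        out = overlay(chain_net, coexpression_results=[res])
        e = [e for e in out.edges if {e.source_id, e.target_id} == {"a", "b"}][0]
        assert e.attributes["coexpression_support"] == 12

    def test_empty_overlay_is_identity(self, chain_net):
        out = overlay(chain_net)
        assert out.nodes == chain_net.nodes
        assert [e.key() for e in out.edges] == [e.key() for e in chain_net.edges]

    def test_node_count_unchanged_and_unresolved_reported(self, chain_net):
        res = CoexpressionResult(("a", "zz_unknown"), ["e1"])
        with pytest.warns(UserWarning, match="could not be resolved"):
            out = overlay(chain_net, coexpression_results=[res],
                          node_values={"b": 1.5, "also_unknown": 2.0})
        assert out.nodes == chain_net.nodes
        assert out.node_attrs["b"]["z"] == 1.5


class TestSifIO:
    def test_round_trip_with_attributes(self, tmp_path):
        net = Network([
            InteractionRecord("T1", "g1", "tf_dna", True, "positive",
                              "transcription", 1e-4,
                              {"conserved": True, "n_sites": 3}, "tfbs"),
            InteractionRecord("g1", "g2", "coexpression", False,
                              attributes={"support": 12}),
            InteractionRecord("p1", "p2", "ppi"),
        ])
        write_sif(net, tmp_path / "n.sif", tmp_path / "n.edges.tsv")
        back = read_sif(tmp_path / "n.sif", tmp_path / "n.edges.tsv")
        orig = sorted(net.edges, key=lambda e: e.key())
        got = sorted(back.edges, key=lambda e: e.key())
        assert [(e.source_id, e.target_id, e.relation_type, e.directed,
                 e.effect, e.mechanism, e.p_value, e.attributes, e.provenance)
                for e in got] == \
            [(e.source_id, e.target_id, e.relation_type, e.directed,
              e.effect, e.mechanism, e.p_value, e.attributes, e.provenance)
             for e in orig]

    def test_sif_text_shape(self, tmp_path):
        net = Network([edge("a", "b", "ppi")])
        write_sif(net, tmp_path / "n.sif")
        assert (tmp_path / "n.sif").read_text() == "a\tppi\tb\n"
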