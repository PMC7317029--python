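import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from clonescreen import network as net
from clonescreen import synthetic
from clonescreen.exceptions import EmptyInputError, InvalidArgumentError


def edge_frame(pairs, types=None):
    rows = []
    for i, (a, b) in enumerate(pairs):
        t = types[i] if types else "physical"
        rows.append({"gene_a": a, "gene_b": b, "type": t, "source": "test"})
    return pd.DataFrame(rows)


def exhaustive_neighborhood_weight(g, v):
    """Brute-force oracle: enumerate all subsets of N[v] for the best k-core."""
    nbhd = sorted(set(g.neighbors(v)) | {v})
    best_k = 0
    for r in range(2, len(nbhd) + 1):
        for subset in itertools.combinations(nbhd, r):
            sub = g.subgraph(subset)
            if sub.number_of_edges() == 0:
                continue
            mindeg = min(d for _, d in sub.degree())
            best_k = max(best_k, mindeg)
    if best_k == 0:
        return 0.0
    # union of all subsets with min degree >= best_k is the best_k-core
    members = set()
    for r in range(2, len(nbhd) + 1):
        for subset in itertools.combinations(nbhd, r):
            sub = g.subgraph(subset)
            if sub.number_of_edges() and \
                    min(d for _, d in sub.degree()) >= best_k:
                members |= set(subset)
    core = g.subgraph(members)
    n = core.number_of_nodes()
    density = 2 * core.number_of_edges() / (n * (n - 1))
    return best_k * density


class TestBuildNetwork:
    def test_no_edges_among_hits_empty(self):
        g = net.build_network({"h1", "h2"}, set(), edge_frame([("x", "y")]))
        assert g.number_of_nodes() == 0

    def test_linker_rule_toy(self):
        # h1-x-h2: x kept as linker; h1-y: y dropped (only one hit neighbor)
        edges = edge_frame([("h1", "x"), ("x", "h2"), ("h1", "y")])
        g = net.build_network({"h1", "h2"}, set(), edges)
        assert set(g.nodes) == {"h1", "h2", "x"}
        assert g.nodes["x"]["linker"]
        assert not g.nodes["h1"]["linker"]

    def test_linker_linker_edges_dropped_by_default(self):
        edges = edge_frame([("h1", "x"), ("x", "h2"), ("h1", "y"),
                            ("y", "h2"), ("x", "y")])
        g = net.build_network({"h1", "h2"}, set(), edges)
        assert not g.has_edge("x", "y")
        g2 = net.build_network({"h1", "h2"}, set(), edges, edge_rule="induced")
        assert g2.has_edge("x", "y")

    def test_lethals_retained(self):
        edges = edge_frame([("h1", "dead"), ("dead", "h2")])
        g = net.build_network({"h1", "h2"}, {"dead"}, edges)
        assert g.nodes["dead"]["lethal"]
        # 'hit' rule drops lethal-lethal edges but keeps hit-lethal ones
        g3 = net.build_network({"h1", "h2"}, {"dead", "dead2"},
                               edge_frame([("h1", "dead"), ("dead", "dead2")]),
                               edge_rule="hit")
        assert g3.has_edge("h1", "dead") and not g3.has_edge("dead", "dead2")

    def test_hit_lethal_overlap_rejected(self):
        with pytest.raises(InvalidArgumentError):
            net.build_network({"a"}, {"a"}, edge_frame([("a", "b")]))

    def test_empty_hits_rejected(self):
        with pytest.raises(EmptyInputError):
            net.build_network(set(), set(), edge_frame([("a", "b")]))

    def test_row_order_and_duplicate_invariance(self):
        pairs = [("h1", "h2"), ("h2", "h3"), ("h1", "x"), ("x", "h3")]
        e1 = edge_frame(pairs)
        e2 = edge_frame(pairs[::-1] + pairs)  # reversed plus duplicates
        g1 = net.build_network({"h1", "h2", "h3"}, set(), e1)
        g2 = net.build_network({"h1", "h2", "h3"}, set(), e2)
        assert set(g1.edges) == set(g2.edges)
        assert set(g1.nodes) == set(g2.nodes)

    def test_parallel_evidence_collapsed_with_precedence(self):
        edges = edge_frame([("h1", "h2"), ("h2", "h1")],
                           types=["interolog", "genetic"])
        g = net.build_network({"h1", "h2"}, set(), edges)
        assert g.number_of_edges() == 1
        data = g.get_edge_data("h1", "h2")
        assert data["types"] == {"genetic", "interolog"}
        assert data["display_type"] == "genetic"

    def test_categories_attached(self):
        g = net.build_network({"h1": {"invasion"}, "h2": {"multilayering"}},
                              set(), edge_frame([("h1", "h2")]))
        assert g.nodes["h1"]["categories"] == ("invasion",)


class TestMcodeWeights:
    def test_k5_hand_value(self):
        w = net.mcode_weights(nx.complete_graph(5))
        assert all(v == pytest.approx(4.0) for v in w.values())

    def test_star_center(self):
        g = nx.star_graph(4)  # center 0, leaves 1..4
        w = net.mcode_weights(g)
        # center: neighborhood is the whole star, 1-core, density 4/10
        assert w[0] == pytest.approx(1 * (2 * 4) / (5 * 4))
        # leaf: neighborhood is a single edge, 1-core of density 1
        assert w[1] == pytest.approx(1.0)

    def test_empty_graph_zero(self):
        g = nx.empty_graph(5)
        assert set(net.mcode_weights(g).values()) == {0.0}

    def test_matches_exhaustive_oracle_small_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            n = int(rng.integers(2, 9))
            g = nx.gnp_random_graph(n, float(rng.uniform(0.1, 0.9)),
                                    seed=int(rng.integers(1e6)))
            w = net.mcode_weights(g)
            for v in g.nodes:
                assert w[v] == pytest.approx(
                    exhaustive_neighborhood_weight(g, v)), (g.edges, v)


class TestMcodeComplexes:
    def test_single_k5(self):
        res = net.mcode_complexes(nx.complete_graph(5))
        assert len(res) == 1
        assert res[0].members == frozenset(range(5))
        assert res[0].density == pytest.approx(1.0)

    def test_bridged_k4s_split(self):
        g = nx.Graph()
        for base in (0, 10):
            g.add_edges_from((base + i, base + j)
                             for i in range(4) for j in range(i + 1, 4))
        g.add_edge(0, 10)
        res = net.mcode_complexes(g, vwp=0.2, haircut=True)
        assert sorted(sorted(c.members) for c in res) == \
            [[0, 1, 2, 3], [10, 11, 12, 13]]

    def test_edgeless_no_complexes(self):
        assert net.mcode_complexes(nx.empty_graph(6)) == []

    def test_invalid_vwp(self):
        with pytest.raises(InvalidArgumentError):
            net.mcode_complexes(nx.complete_graph(4), vwp=1.0)

    def test_complex_density_at_least_graph_density(self):
        edges, truth = synthetic.gen_interactome(
            [f"h{i}" for i in range(20)], set(), 10,
            planted_complexes=[(5, 1.0), (4, 1.0)], p_background=0.05,
            n_linkers=2, seed=3)
        g = net.build_network({f"h{i}" for i in range(20)}, set(), edges,
                              edge_rule="induced")
        whole = 2 * g.number_of_edges() / (
            g.number_of_nodes() * (g.number_of_nodes() - 1))
        for c in net.mcode_complexes(g):
            assert c.density >= whole

    def test_planted_clique_recovery(self):
        hit_genes = [f"h{i:02d}" for i in range(30)]
        edges, truth = synthetic.gen_interactome(
            hit_genes, {"let1"}, 20, planted_complexes=[(6, 1.0), (6, 1.0)],
            p_background=0.01, n_linkers=3, seed=7)
        g = nx.from_pandas_edgelist(edges, "gene_a", "gene_b")
        res = net.mcode_complexes(g)
        top2 = {c.members for c in res[:2]}
        assert top2 == {frozenset(s) for s in truth.complexes}


class TestHubs:
    def test_star_center_top1(self):
        g = nx.star_graph(5)
        assert net.hubs(g, 1) == [0]

    def test_tie_lexicographic(self):
        g = nx.Graph([("b", "c"), ("a", "c")])  # a and b both degree 1
        assert net.hubs(g, 3) == ["c", "a", "b"]

    def test_matches_sort_oracle(self):
        g = nx.gnp_random_graph(20, 0.3, seed=5)
        expect = sorted(g.nodes, key=lambda v: (-g.degree(v), str(v)))[:5]
        assert net.hubs(g, 5) == expect

    def test_errors(self):
        with pytest.raises(EmptyInputError):
            net.hubs(nx.Graph(), 1)
        with pytest.raises(InvalidArgumentError):
            net.hubs(nx.complete_graph(3), 0)


class TestBipartiteCount:
    def test_no_cross_edges(self):
        assert net.bipartite_count({"a"}, {"b"}, edge_frame([("a", "a2")])) \
            == (0, 0, 0)

    def test_complete_bipartite_3x4(self):
        A = [f"a{i}" for i in range(3)]
        B = [f"b{i}" for i in range(4)]
        pairs = [(a, b) for a in A for b in B]
        assert net.bipartite_count(A, B, edge_frame(pairs)) == (12, 3, 4)

    def test_matches_double_loop(self):
        rng = np.random.default_rng(8)
        nodes = [f"n{i}" for i in range(12)]
        pairs = [(nodes[i], nodes[j]) for i in range(12) for j in range(i + 1, 12)
                 if rng.random() < 0.4]
        A, B = set(nodes[:5]), set(nodes[5:9])
        expect_pairs = {tuple(sorted(p)) for p in pairs
                        if (p[0] in A) != (p[1] in A)
                        and (p[0] in A | B and p[1] in A | B)}
        expect = (len(expect_pairs),
                  len({x for p in expect_pairs for x in p if x in A}),
                  len({x for p in expect_pairs for x in p if x in B}))
        assert net.bipartite_count(A, B, edge_frame(pairs)) == expect


class TestIO:
    def test_edge_list_round_trip_roles(self, tmp_path):
        edges = edge_frame([("h1", "h2"), ("h1", "x"), ("x", "h2")])
        g = net.build_network({"h1", "h2"}, set(), edges)
        p = tmp_path / "edges.tsv"
        net.write_edge_list(g, p)
        back = pd.read_csv(p, sep="\t")
        assert len(back) == g.number_of_edges()
        assert set(back["a_role"]) <= {"hit", "lethal", "linker", "other"}

    def test_graphml_export(self, tmp_path):
        g = net.build_network({"h1", "h2"}, set(), edge_frame([("h1", "h2")]))
        p = tmp_path / "g.graphml"
        net.write_graphml(g, p)
        back = nx.read_graphml(p)
        assert set(back.nodes) == {"h1", "h2"}
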