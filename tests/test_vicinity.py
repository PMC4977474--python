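import networkx as nx
import numpy as np
import pytest

from coexnet.io import GoISet
from coexnet.thresholding import UnweightedNetwork
from coexnet.vicinity import (
    Clique,
    clique_vicinity,
    goi_analysis,
    maximal_cliques,
    subnetwork_density,
    vertex_vicinity,
)

import oracles
from conftest import random_graph


def as_net(g, m=None):
    return UnweightedNetwork(g, m if m is not None else g.number_of_nodes())


class TestMaximalCliques:
    def test_triangle(self):
        assert maximal_cliques(nx.complete_graph(3)) == [Clique((0, 1, 2))]

    def test_path(self):
        cliques = maximal_cliques(nx.path_graph(3))
        assert {c.members for c in cliques} == {(0, 1), (1, 2)}

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_powerset_oracle(self, seed):
        g = random_graph(10 + seed % 3, 0.35, seed=seed)
        expected = oracles.maximal_cliques_powerset(g)
        got = {frozenset(c.members) for c in maximal_cliques(g)}
        assert got == expected

    def test_deterministic_order(self):
        g = random_graph(12, 0.4, seed=99)
        assert maximal_cliques(g) == maximal_cliques(g)

    def test_edgeless_graph(self):
        g = nx.empty_graph(4)
        assert maximal_cliques(g) == []

    def test_clique_invariants(self):
        with pytest.raises(ValueError):
            Clique(("a",))
        with pytest.raises(ValueError):
            Clique(("a", "a"))


class TestVertexVicinity:
    def test_star_center(self):
        net = as_net(nx.star_graph(4))
        vn = vertex_vicinity(net, 0)
        assert set(vn.members) == {0, 1, 2, 3, 4}
        assert vn.density == pytest.approx(0.4)  # 2(n-1)/(n(n-1)) for n=5

    def test_degree_one_gene(self):
        g = nx.Graph([("a", "b"), ("b", "c")])
        vn = vertex_vicinity(as_net(g), "a")
        assert set(vn.members) == {"a", "b"} and vn.density == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_members_match_neighbour_scan(self, seed):
        g = random_graph(20, 0.2, seed=seed)
        v = sorted(g.nodes)[0]
        vn = vertex_vicinity(as_net(g), v)
        expected = {v} | {u for u in g.nodes if g.has_edge(u, v)}
        assert set(vn.members) == expected
        if len(vn.members) >= 2:
            assert vn.density == pytest.approx(oracles.induced_density(g, vn.members))

    def test_absent_gene_rejected(self):
        with pytest.raises(KeyError, match="ghost"):
            vertex_vicinity(as_net(nx.path_graph(3)), "ghost")


class TestCliqueVicinity:
    def hand_graph(self):
        # a-b clique; c, d adjacent to both; e adjacent to a only; f isolated-ish
        return nx.Graph([
            ("a", "b"), ("a", "c"), ("b", "c"), ("a", "d"), ("b", "d"),
            ("a", "e"), ("e", "f"),
        ])

    def test_common_neighbours(self):
        vn = clique_vicinity(as_net(self.hand_graph()), Clique(("a", "b")))
        # oracle: intersection of the two neighbourhoods
        g = self.hand_graph()
        common = (set(g.neighbors("a")) & set(g.neighbors("b"))) | {"a", "b"}
        assert set(vn.members) == common == {"a", "b", "c", "d"}

    def test_non_clique_anchor_rejected(self):
        g = self.hand_graph()
        with pytest.raises(ValueError, match="not a clique"):
            clique_vicinity(as_net(g), Clique(("c", "d")))

    def test_clique_equal_to_component(self):
        g = nx.complete_graph(4)
        vn = clique_vicinity(as_net(g), Clique((0, 1, 2, 3)))
        assert set(vn.members) == {0, 1, 2, 3} and vn.density == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_all_members_adjacent_to_anchor(self, seed):
        g = random_graph(25, 0.3, seed=seed)
        for c in maximal_cliques(g)[:5]:
            vn = clique_vicinity(as_net(g), c)
            for member in vn.members:
                if member in c.members:
                    continue
                assert all(g.has_edge(member, a) for a in c.members)


class TestDensity:
    def test_any_clique_is_one(self):
        assert subnetwork_density(nx.complete_graph(5), range(5)) == 1.0

    def test_31_vertices_missing_six_edges(self):
        g = nx.complete_graph(31)
        edges = list(g.edges())[:6]
        g.remove_edges_from(edges)
        d = subnetwork_density(g, range(31))
        assert d == pytest.approx(459 / 465)
        assert f"{d:.4f}" == "0.9871"

    def test_path(self):
        assert subnetwork_density(nx.path_graph(3), [0, 1, 2]) == pytest.approx(2 / 3)

    def test_too_few_genes(self):
        with pytest.raises(ValueError):
            subnetwork_density(nx.path_graph(3), [0])


def planted_graph():
    """Ten mutually connected genes of interest + background structure."""
    g = nx.complete_graph([f"q{i}" for i in range(10)])
    g.add_edges_from([(f"q{i}", "hub") for i in range(10)])  # common neighbour
    g.add_edges_from([("x", "y"), ("y", "z"), ("q0", "x")])
    return g


class TestGoIAnalysis:
    def test_clique_mode_recovers_planted_module(self):
        net = as_net(planted_graph())
        gois = GoISet([f"q{i}" for i in range(10)])
        res = goi_analysis(net, gois, mode="clique_based")
        assert len(res.vns) == 1
        vn = res.vns[0]
        assert vn.goi_count == 10
        assert set(vn.members) == {f"q{i}" for i in range(10)} | {"hub"}
        assert vn.density == pytest.approx(1.0)  # hub joins every member

    def test_disconnected_gois_fall_back_to_vertex_vns(self):
        g = nx.Graph([("a", "n1"), ("b", "n2"), ("n1", "n2")])
        res = goi_analysis(as_net(g), GoISet(["a", "b"]), mode="clique_based")
        assert len(res.vns) == 2
        assert {vn.anchor for vn in res.vns} == {("a",), ("b",)}

    def test_per_gene_mode_one_vn_each(self):
        net = as_net(planted_graph())
        res = goi_analysis(net, GoISet(["q0", "x"]), mode="per_gene")
        assert len(res.vns) == 2
        by_anchor = {vn.anchor[0]: vn for vn in res.vns}
        assert set(by_anchor["x"].members) == {"x", "q0", "y"}

    def test_per_gene_mode_warns_on_long_list(self, caplog):
        g = nx.complete_graph([f"g{i}" for i in range(25)])
        with caplog.at_level("WARNING"):
            goi_analysis(as_net(g), GoISet([f"g{i}" for i in range(25)]), mode="per_gene")
        assert "at most 20" in caplog.text

    def test_unmatched_gois_reported_not_fatal(self, caplog):
        net = as_net(planted_graph())
        with caplog.at_level("WARNING"):
            res = goi_analysis(net, GoISet(["q0", "ghost"]), mode="per_gene")
        assert res.unmatched_gois == ["ghost"]
        assert len(res.vns) == 1

    def test_zero_matched_gois(self):
        res = goi_analysis(as_net(planted_graph()), GoISet(["nope"]), mode="clique_based")
        assert res.vns == [] and res.matched_gois == set()

    def test_vn_table_rows(self):
        res = goi_analysis(as_net(planted_graph()), GoISet(["q0", "q1"]))
        rows = res.vn_table()
        assert rows and rows[0][0] == 1
        for idx, size, n_goi, density in rows:
            vn = next(v for v in res.vns if v.index == idx)
            assert size == len(vn.members) and n_goi == vn.goi_count

    @pytest.mark.parametrize("seed", range(8))
    def test_densities_match_brute_force_on_all_vns(self, seed):
        g = random_graph(30, 0.25, seed=seed)
        nodes = sorted(g.nodes)[:8]
        res = goi_analysis(as_net(g), GoISet(nodes), mode="clique_based")
        for vn in res.vns:
            if len(vn.members) >= 2:
                assert vn.density == pytest.approx(
                    oracles.induced_density(g, vn.members)
                )

    @pytest.mark.parametrize("seed", range(6))
    def test_goi_subgraph_cliques_equal_full_network_restriction(self, seed):
        # enumerating cliques inside the GoI-induced subgraph loses nothing
        # relative to enumerating in the whole graph and intersecting with GoIs
        g = random_graph(40, 0.2, seed=seed)
        gois = sorted(g.nodes)[:12]
        sub = g.subgraph(gois)
        from_sub = {frozenset(c.members) for c in maximal_cliques(sub)}
        restricted = oracles.maximal_cliques_powerset(sub)
        assert from_sub == restricted

    def test_fuzzy_clique_label(self):
        g = nx.complete_graph(10)
        g.remove_edge(0, 1)
        net = as_net(g)
        res = goi_analysis(net, GoISet([2, 3, 4]), mode="clique_based")
        vn = res.vns[0]
        assert 0.85 <= vn.density < 1.0
        assert vn.is_fuzzy_clique
        assert vn.missing_edges == 1
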