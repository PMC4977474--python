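from fractions import Fraction

import networkx as nx
import numpy as np
import pytest

from coexnet.association import compute_association_matrix, get_measure, sort_association_pairs
from coexnet.io import ExpressionMatrix
from coexnet.simulate import (
    generate_modular_dataset,
    generate_powerlaw_degree_sample,
    generate_reference_graph,
)
from coexnet.thresholding import UnweightedNetwork, initial_threshold_list
from coexnet.topology import (
    DegreeDistribution,
    NetworkStatsRow,
    SelectionCriteria,
    component_stats,
    degree_distribution,
    evaluate_thresholds,
    fit_power_law,
    mean_cluster_coefficient,
    mean_path_length,
    select_best_threshold,
    small_world_report,
)

import oracles
from conftest import random_graph


def as_net(g, m=None):
    return UnweightedNetwork(g, m if m is not None else g.number_of_nodes())


# The seven published network-statistics rows of the worked beetle example:
# thresh, R2, slope, meanCC, meanPath, %used, %bigComp.
TABLE5 = [
    NetworkStatsRow(0.956, 0.84, -1.71, 0.44, 6.89, 21, 22),
    NetworkStatsRow(0.919, 0.90, -1.62, 0.37, 11.13, 50, 85),
    NetworkStatsRow(0.882, 0.89, -1.45, 0.38, 7.19, 72, 94),
    NetworkStatsRow(0.845, 0.86, -1.24, 0.40, 5.66, 86, 97),
    NetworkStatsRow(0.808, 0.82, -1.05, 0.42, 4.71, 94, 99),
    NetworkStatsRow(0.771, 0.77, -0.93, 0.44, 4.04, 98, 100),
    NetworkStatsRow(0.734, 0.71, -0.85, 0.47, 3.55, 99, 100),
]


class TestDegreeDistribution:
    def test_triangle(self):
        dd = degree_distribution(as_net(nx.complete_graph(3)))
        assert dd.p_k == {2: 1.0}

    def test_star(self):
        dd = degree_distribution(as_net(nx.star_graph(4)))
        assert dd.p_k == {1: 0.8, 4: 0.2}

    def test_matches_brute_force_tally(self):
        g = random_graph(100, 0.05, seed=8)
        g.remove_nodes_from(list(nx.isolates(g)))
        dd = degree_distribution(as_net(g))
        assert dd.counts == oracles.degree_tally(g)

    @pytest.mark.parametrize("seed", range(5))
    def test_probabilities_sum_to_one_exactly(self, seed):
        g = random_graph(40, 0.1, seed=seed)
        g.remove_nodes_from(list(nx.isolates(g)))
        dd = degree_distribution(as_net(g))
        assert sum(Fraction(c, dd.n) for c in dd.counts.values()) == 1

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            degree_distribution(as_net(nx.Graph()))


class TestPowerLawFit:
    def test_exact_power_law_recovered(self):
        ks = np.arange(1, 51)
        weights = ks**-2.0
        dd = DegreeDistribution({int(k): float(w) for k, w in zip(ks, weights)})
        fit = fit_power_law(dd)
        assert fit.a == pytest.approx(2.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.a == -fit.slope

    def test_uniform_distribution_fails_exponent_gate(self):
        dd = DegreeDistribution({k: 10 for k in range(1, 11)})
        fit = fit_power_law(dd)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert not (1 < fit.a < 3)

    def test_sampled_exponent_recovery(self):
        dd = generate_powerlaw_degree_sample(a=2.5, k_max=100, n_draws=100_000, seed=5)
        fit = fit_power_law(dd)
        assert fit.a == pytest.approx(2.5, abs=0.1)

    def test_few_support_points_unreliable(self):
        fit = fit_power_law(DegreeDistribution({1: 5, 2: 3}))
        assert not fit.reliable


class TestClusterCoefficient:
    @pytest.mark.parametrize(
        "graph,expected",
        [
            (nx.complete_graph(3), 1.0),
            (nx.path_graph(3), 0.0),
            (nx.complete_graph(4), 1.0),
        ],
    )
    def test_known_graphs(self, graph, expected):
        assert mean_cluster_coefficient(as_net(graph)) == pytest.approx(expected)

    def test_k4_minus_edge(self):
        g = nx.complete_graph(4)
        g.remove_edge(0, 1)
        # deg(0)=deg(1)=2, neighbours {2,3} connected -> CC=1; deg(2)=deg(3)=3
        # with 2 of 3 neighbour pairs connected -> CC=2/3; mean = (1+1+2/3+2/3)/4
        assert mean_cluster_coefficient(as_net(g)) == pytest.approx(5 / 6)
        assert mean_cluster_coefficient(as_net(g)) == pytest.approx(oracles.mean_cc(g))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_triangle_count_oracle(self, seed):
        g = random_graph(30, 0.15, seed=seed)
        assert mean_cluster_coefficient(as_net(g)) == pytest.approx(
            oracles.mean_cc(g), abs=1e-12
        )


class TestPathLength:
    def test_complete_graph(self):
        assert mean_path_length(as_net(nx.complete_graph(4))) == 1.0

    def test_path_graph(self):
        assert mean_path_length(as_net(nx.path_graph(3))) == pytest.approx(4 / 3)

    def test_cross_component_pairs_excluded(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        assert mean_path_length(as_net(g)) == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bfs_oracle(self, seed):
        g = random_graph(30, 0.1, seed=seed)
        g.remove_nodes_from(list(nx.isolates(g)))
        if g.number_of_edges() == 0:
            pytest.skip("edgeless draw")
        assert mean_path_length(as_net(g)) == pytest.approx(
            oracles.mean_path(g), abs=1e-12
        )


class TestComponents:
    def test_connected(self):
        assert component_stats(as_net(nx.path_graph(5))) == (1, 100.0)

    def test_95_5_split(self):
        g = nx.disjoint_union(nx.path_graph(95), nx.path_graph(5))
        n, pct = component_stats(as_net(g))
        assert (n, pct) == (2, 95.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bfs_labelling_oracle(self, seed):
        g = random_graph(200, 0.008, seed=seed)
        comps = oracles.components(g)
        n, pct = component_stats(as_net(g))
        assert n == len(comps)
        assert pct == pytest.approx(100.0 * max(map(len, comps)) / 200)


class TestEvaluateThresholds:
    def test_planted_dataset_rows_nested_and_monotone(self, planted_dataset):
        X, _ = planted_dataset
        A = compute_association_matrix(X, get_measure("SP"))
        s = sort_association_pairs(A)
        tl = initial_threshold_list(s, X.m)
        rows = evaluate_thresholds(s, tl, X.m)
        assert len(rows) == 7
        used = [r.pct_used for r in rows if not r.degenerate]
        assert all(a <= b + 1e-12 for a, b in zip(used, used[1:]))

    def test_complete_agreement_data(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=6)
        V = np.array([base + rng.normal(0, 1e-6, size=6) for _ in range(8)])
        X = ExpressionMatrix(
            [f"g{i}" for i in range(8)], [f"s{j}" for j in range(6)], V
        )
        A = compute_association_matrix(X, get_measure("SP"))
        s = sort_association_pairs(A)
        tl = initial_threshold_list(s, 8)
        rows = evaluate_thresholds(s, tl, 8)
        assert all(r.pct_big_comp == 100.0 for r in rows if not r.degenerate)


class TestSelection:
    def test_published_rows_select_best_and_alternate(self):
        sel = select_best_threshold(TABLE5)
        assert sel.best == 0.808
        assert sel.alternates == [0.845]
        # narrative rejections: fragmented above 0.845, poor fit below 0.808
        assert any("component" in r for r in sel.reasons[0.956])
        assert any("component" in r for r in sel.reasons[0.919])
        assert any("component" in r for r in sel.reasons[0.882])
        assert any("determination" in r for r in sel.reasons[0.771])
        assert any("determination" in r for r in sel.reasons[0.734])

    def test_single_passing_row(self):
        rows = [NetworkStatsRow(0.8, 0.9, -1.5, 0.4, 4.0, 90, 99)]
        sel = select_best_threshold(rows)
        assert sel.best == 0.8 and sel.alternates == []

    def test_fragmented_rows_select_nothing(self):
        rows = [
            NetworkStatsRow(t, 0.9, -1.5, 0.4, 4.0, 90, 50.0) for t in (0.9, 0.8)
        ]
        sel = select_best_threshold(rows)
        assert sel.best is None and sel.alert is not None
        assert all(rows_t in sel.reasons for rows_t in (0.9, 0.8))

    def test_exclusive_exponent_interval(self):
        rows = [NetworkStatsRow(0.8, 0.9, -1.0, 0.4, 4.0, 90, 99)]
        assert select_best_threshold(rows).best is None  # a = 1 is not inside (1,3)
        rows = [NetworkStatsRow(0.8, 0.9, -3.0, 0.4, 4.0, 90, 99)]
        assert select_best_threshold(rows).best is None

    def test_tie_on_used_goes_to_more_stringent(self):
        rows = [
            NetworkStatsRow(0.9, 0.9, -1.5, 0.4, 4.0, 90, 99),
            NetworkStatsRow(0.8, 0.9, -1.5, 0.4, 4.0, 90, 99),
        ]
        assert select_best_threshold(rows).best == 0.9

    def test_pure_function_of_inputs(self):
        assert select_best_threshold(TABLE5) == select_best_threshold(TABLE5)

    def test_configurable_gates(self):
        sel = select_best_threshold(TABLE5, SelectionCriteria(r2_min=0.70))
        # relaxing R2 admits 0.771 and 0.734 only if exponent passes; it does not
        assert sel.best == 0.808


class TestSmallWorld:
    def test_ring_rewire_flagged(self):
        g = generate_reference_graph("ring_rewire", seed=11, n=500, k=6, p=0.05)
        rep = small_world_report(as_net(g))
        assert rep.small_world and rep.cc_ratio >= 5

    def test_er_not_flagged(self):
        g = generate_reference_graph("er", seed=13, n=500, k_mean=6)
        rep = small_world_report(as_net(g))
        assert not rep.small_world
        assert rep.cc_ratio == pytest.approx(1.0, abs=0.75)  # CC ~ k/(n-1)

    def test_complete_graph_matches_its_own_random_baseline(self):
        # a complete graph IS the density-1 random graph: CC ratio is exactly 1
        # and the path ratio is below 1, so the advisory cannot flag it
        rep = small_world_report(as_net(nx.complete_graph(20)))
        assert rep.cc_ratio == pytest.approx(1.0)
        assert rep.path_ratio < 1.0
        assert not rep.small_world

    def test_sparse_graph_not_assessable(self):
        g = nx.Graph([("a", "b"), ("c", "d")])  # mean degree 1
        rep = small_world_report(as_net(g))
        assert not rep.assessable
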