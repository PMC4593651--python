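import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import workload_directed_bf, workload_undirected_bf
from conftest import random_graph
from starnet import (
    NeighborhoodPartition,
    moment_stats,
    neighborhood_partition,
    planted_neighborhood,
    star_value_directed,
    star_value_undirected,
    star_values,
    summary_stats,
    sv_distribution,
    sv_table,
    workload_directed,
    workload_undirected,
)


class TestUndirected:
    @pytest.mark.parametrize(
        "k,m,expected_L",
        [(4, 0, 6), (4, 6, 0), (3, 1, 2)],  # star, clique hub, one shortcut
    )
    def test_workload_on_planted_neighborhoods(self, k, m, expected_L):
        g = planted_neighborhood(k, m, seed=0)
        assert workload_undirected(g, "hub") == expected_L

    @pytest.mark.parametrize("k,m,expected", [(4, 0, 0.75), (5, 10, 0.0), (3, 1, 4 / 9)])
    def test_star_value_on_planted_neighborhoods(self, k, m, expected):
        g = planted_neighborhood(k, m, seed=0)
        assert star_value_undirected(g, "hub") == pytest.approx(expected)

    def test_degree_one_vertex_scores_zero(self):
        g = nx.Graph([("a", "b")])
        assert star_value_undirected(g, "a") == 0.0

    def test_degree_zero_vertex_undefined(self):
        g = nx.Graph([("a", "b")])
        g.add_node("z")
        with pytest.raises(ValueError):
            star_value_undirected(g, "z")
        assert "z" not in star_values(g)

    def test_workload_matches_pairwise_enumeration_on_random_graphs(self):
        for seed in range(30):
            g = random_graph(10, 0.35, seed)
            for v in g.nodes:
                if g.degree(v) > 0:
                    assert workload_undirected(g, v) == workload_undirected_bf(g, v)


class TestDirected:
    def test_partition_of_mixed_neighborhood(self):
        d = nx.DiGraph([("a", "v"), ("v", "b"), ("v", "c"), ("c", "v")])
        p = neighborhood_partition(d, "v")
        assert (set(p.S), set(p.T), set(p.C)) == ({"a"}, {"b"}, {"c"})

    def test_all_reciprocal_neighborhood(self):
        d = nx.DiGraph()
        for u in "abc":
            d.add_edge(u, "v")
            d.add_edge("v", u)
        p = neighborhood_partition(d, "v")
        assert not p.S and not p.T and set(p.C) == {"a", "b", "c"}

    def test_source_target_arc_counted_once(self):
        d = nx.DiGraph([("s", "v"), ("v", "t"), ("c", "v"), ("v", "c"), ("s", "t")])
        p = neighborhood_partition(d, "v")
        assert p.m == 1.0

    def test_reverse_target_source_arc_not_counted(self):
        d = nx.DiGraph([("s", "v"), ("v", "t"), ("t", "s")])
        assert neighborhood_partition(d, "v").m == 0.0

    @pytest.mark.parametrize(
        "S,T,C,m,expected_L",
        [(1, 1, 0, 0.0, 1.0), (0, 0, 4, 6.0, 0.0), (2, 1, 1, 0.0, 5.0)],
    )
    def test_workload_formula_terms(self, S, T, C, m, expected_L):
        p = NeighborhoodPartition(
            "v",
            frozenset(f"s{i}" for i in range(S)),
            frozenset(f"t{i}" for i in range(T)),
            frozenset(f"c{i}" for i in range(C)),
            m,
        )
        assert workload_directed(p) == pytest.approx(expected_L)

    def test_single_mediated_pair_star_value(self):
        p = NeighborhoodPartition("v", frozenset({"s"}), frozenset({"t"}), frozenset(), 0.0)
        assert star_value_directed(p) == pytest.approx(0.4)

    def test_reciprocal_star_matches_undirected_value(self):
        p = NeighborhoodPartition("v", frozenset(), frozenset(), frozenset("abcd"), 0.0)
        assert star_value_directed(p) == pytest.approx(0.75)

    def test_reciprocal_clique_hub_scores_zero(self):
        d = nx.DiGraph()
        for u in "vabc":
            for w in "vabc":
                if u != w:
                    d.add_edge(u, w)
        assert star_value_directed(neighborhood_partition(d, "v")) == pytest.approx(0.0)

    def test_empty_neighborhood_undefined(self):
        d = nx.DiGraph([("a", "b")])
        d.add_node("z")
        with pytest.raises(ValueError):
            star_value_directed(neighborhood_partition(d, "z"))

    def test_workload_matches_mediated_pair_enumeration(self):
        for seed in range(30):
            d = random_graph(9, 0.3, seed, directed=True)
            for v in d.nodes:
                p = neighborhood_partition(d, v)
                if not p.is_empty:
                    assert workload_directed(p) == pytest.approx(workload_directed_bf(d, v))

    def test_fully_reciprocal_digraph_agrees_with_undirected_vertexwise(self):
        for seed in range(20):
            g = random_graph(10, 0.4, seed)
            d = nx.DiGraph()
            d.add_nodes_from(g.nodes)
            for u, v in g.edges():
                d.add_edge(u, v)
                d.add_edge(v, u)
            for v in g.nodes:
                if g.degree(v) == 0:
                    continue
                assert star_value_directed(neighborhood_partition(d, v)) == pytest.approx(
                    star_value_undirected(g, v)
                )


class TestProperties:
    @given(st.integers(2, 20), st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_sv_strictly_decreases_as_spokes_interconnect(self, k, data):
        """At fixed hub degree, each added intra-spoke edge lowers SV."""
        max_m = k * (k - 1) // 2
        m = data.draw(st.integers(0, max_m - 1))
        seed = data.draw(st.integers(0, 10_000))
        low = star_value_undirected(planted_neighborhood(k, m + 1, seed), "hub")
        high = star_value_undirected(planted_neighborhood(k, m, seed), "hub")
        assert low < high

    @pytest.mark.parametrize("k", range(2, 51))
    def test_pure_star_hub_value_is_one_minus_one_over_k(self, k):
        g = planted_neighborhood(k, 0)
        assert star_value_undirected(g, "hub") == pytest.approx(1 - 1 / k, abs=1e-12)


class TestDistributionsAndMoments:
    def test_clique_mass_in_leftmost_bin(self, k4):
        hist = sv_distribution(k4, bins=20)
        assert hist["frequency"].iloc[0] == pytest.approx(1.0)
        assert hist["frequency"].sum() == pytest.approx(1.0)

    def test_star_splits_between_leftmost_and_high_bin(self):
        g = planted_neighborhood(4, 0)
        hist = sv_distribution(g, bins=20)
        # 4 leaves at SV=0, hub at SV=0.75 (bin [0.75, 0.80))
        assert hist["frequency"].iloc[0] == pytest.approx(0.8)
        assert hist["frequency"].iloc[15] == pytest.approx(0.2)

    def test_out_of_range_values_clipped(self):
        hist = sv_distribution([-0.1, 0.5, 1.2], bins=10)
        assert hist["frequency"].iloc[0] == pytest.approx(1 / 3)
        assert hist["frequency"].iloc[-1] == pytest.approx(1 / 3)

    def test_empty_distribution_rejected(self):
        with pytest.raises(ValueError):
            sv_distribution([])

    def test_symmetric_sample_has_zero_skewness(self):
        skew, _ = moment_stats([-1.0, 0.0, 1.0])
        assert skew == pytest.approx(0.0, abs=1e-12)

    def test_bernoulli_like_sample_skewness(self):
        skew, _ = moment_stats([0.0, 0.0, 0.0, 1.0])
        assert skew == pytest.approx(2 / math.sqrt(3), abs=1e-9)  # = 1.1547...

    def test_gaussian_sample_near_zero_excess_kurtosis(self):
        x = np.random.default_rng(0).normal(size=100_000)
        skew, kurt = moment_stats(x)
        assert abs(skew) < 0.05 and abs(kurt) < 0.1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            moment_stats([1.0, 1.0, 1.0])

    def test_weighted_moments_match_expanded_sample(self):
        xs = [0.0, 1.0]
        sw, kw = moment_stats(xs, weights=[3, 1])
        se, ke = moment_stats([0.0, 0.0, 0.0, 1.0])
        assert sw == pytest.approx(se) and kw == pytest.approx(ke)


class TestSummaryStats:
    def test_five_cycle_row(self, five_cycle):
        s = summary_stats(five_cycle)
        assert s["n_vertices"] == 5 and s["n_edges_unique"] == 5
        assert s["n_edges_symmetric"] == 10
        assert s["diameter"] == 2
        assert s["characteristic_path_length"] == pytest.approx(1.5)
        assert s["mean_clustering"] == pytest.approx(0.0)
        assert s["mean_star_value"] == pytest.approx(0.5)

    def test_complete_graph_row(self, k4):
        s = summary_stats(k4)
        assert s["diameter"] == 1
        assert s["mean_clustering"] == pytest.approx(1.0)
        assert s["mean_star_value"] == pytest.approx(0.0)

    def test_directed_uses_strong_component(self):
        d = nx.DiGraph([("a", "b"), ("b", "c"), ("c", "a"), ("c", "x")])
        s = summary_stats(d)
        assert s["n_vertices"] == 3  # pendant x unreachable back

    def test_sv_table_schema_and_values(self, five_cycle):
        t = sv_table(five_cycle)
        assert list(t.columns) == [
            "vertex", "n_source_only", "n_target_only", "n_reciprocal",
            "m", "workload", "star_value",
        ]
        assert (t["star_value"] == 0.5).all()
        assert (t["n_reciprocal"] == 2).all()
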