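"""Network construction and topology-score tests."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netprio import (
    GeneSet,
    betweenness_scores,
    build_network,
    degree_scores,
    network_rank_score,
    rank_transform,
    rescale_ranks,
    seed_distance_scores,
)
from conftest import random_network
from oracles import bfs_distances, brute_force_betweenness, graph_to_adj


class TestBuildNetwork:
    def test_dedup_and_self_loop_drop(self):
        net = build_network([[("a", "b"), ("b", "a"), ("a", "b"), ("c", "c")]])
        assert net.nodes == {"a", "b"}
        assert net.n_edges == 1
        assert net.report.n_self_loops == 1
        assert net.report.n_duplicates == 2

    def test_simple_path(self):
        net = build_network([[("a", "b"), ("b", "c")]])
        assert net.n_nodes == 3 and net.n_edges == 2

    def test_union_of_overlapping_tables_matches_set_union(self):
        rng = np.random.default_rng(5)
        genes = list("abcdef")
        tables = []
        for _ in range(5):
            rows = [tuple(rng.choice(genes, 2, replace=False)) for _ in range(6)]
            tables.append(pd.DataFrame(rows))
        expected = {frozenset(r) for t in tables for r in t.itertuples(index=False)}
        net = build_network(tables)
        assert net.n_edges == len(expected)

    def test_alias_mapping_applied_before_dedup(self):
        net = build_network([[("a", "b"), ("a-alias", "b")]], alias_map={"a-alias": "a"})
        assert net.n_edges == 1

    def test_empty_after_filtering_raises(self):
        with pytest.raises(ValueError, match="empty network"):
            build_network([[("x", "x"), ("", "y")]])

    def test_invalid_rows_counted(self):
        net = build_network([[("a", "b"), ("", "b"), (None, "c")]])
        assert net.report.n_invalid == 2


class TestDegree:
    def test_star_and_path(self, star_net, path_net):
        d = degree_scores(star_net)
        assert d["h"] == 4 and (d.drop("h") == 1).all()
        assert degree_scores(path_net).tolist() == [1, 2, 1]

    def test_matches_adjacency_row_sums(self):
        net = random_network(np.random.default_rng(0), 20, 0.2)
        a = nx.to_numpy_array(net.graph, nodelist=net.node_list)
        assert (degree_scores(net).to_numpy() == a.sum(axis=1)).all()


class TestBetweenness:
    def test_path_center(self, path_net):
        cb = betweenness_scores(path_net)
        assert cb["b"] == 1.0 and cb["a"] == cb["c"] == 0.0

    def test_four_cycle_all_half(self):
        net = build_network([[("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")]])
        assert (betweenness_scores(net) == 0.5).all()

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_enumeration_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        net = random_network(rng, int(rng.integers(5, 13)), float(rng.uniform(0.15, 0.5)))
        oracle = brute_force_betweenness(graph_to_adj(net.graph))
        got = betweenness_scores(net)
        for v, expected in oracle.items():
            assert got[v] == pytest.approx(expected, abs=1e-9)


class TestSeedDistance:
    def test_path_with_two_seeds(self, path_net):
        seeds = GeneSet("s", ["a", "c"])
        c_spl, n = seed_distance_scores(path_net, seeds)
        assert c_spl["b"] == 1.0 and c_spl["a"] == 1.0 and (n == 2).all()

    def test_unreachable_component_flagged(self):
        net = build_network([[("a", "b"), ("x", "y")]])
        c_spl, n = seed_distance_scores(net, GeneSet("s", ["a"]))
        assert np.isnan(c_spl["x"]) and n["x"] == 0 and n["a"] == 1

    def test_no_seed_in_network_raises(self, path_net):
        with pytest.raises(ValueError, match="no seed"):
            seed_distance_scores(path_net, GeneSet("s", ["zzz"]))

    def test_matches_bfs_oracle(self):
        rng = np.random.default_rng(7)
        net = random_network(rng, 15, 0.25)
        seeds = GeneSet("s", rng.choice(net.node_list, 3, replace=False))
        adj = graph_to_adj(net.graph)
        c_spl, n = seed_distance_scores(net, seeds)
        for v in net.node_list:
            dists = [bfs_distances(adj, s).get(v) for s in seeds]
            dists = [d for d in dists if d is not None]
            if dists:
                assert c_spl[v] == pytest.approx(np.mean(dists))
            else:
                assert np.isnan(c_spl[v])

    def test_exclude_self_drops_zero_distance(self, path_net):
        seeds = GeneSet("s", ["a", "c"])
        c_spl, _ = seed_distance_scores(path_net, seeds, exclude_self=True)
        assert c_spl["a"] == 2.0  # only the other seed counts


class TestRankTransform:
    def test_tie_averaging(self):
        r = rank_transform(pd.Series({"a": 5, "b": 3, "c": 5}), "better-is-high").ranks
        assert r["a"] == r["c"] == 1.5 and r["b"] == 3

    def test_better_is_low_identity(self):
        s = pd.Series(np.arange(5.0), index=list("abcde"))
        assert rank_transform(s, "better-is-low").ranks.tolist() == [1, 2, 3, 4, 5]

    def test_nan_genes_share_worst_positions(self):
        s = pd.Series({"a": 1.0, "b": np.nan, "c": 2.0, "d": np.nan})
        r = rank_transform(s).ranks
        assert r["b"] == r["d"] == 3.5
        assert r.sum() == 10  # N(N+1)/2

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=100))
    def test_rank_sum_closed_form(self, values):
        s = pd.Series(values)
        r = rank_transform(s, "better-is-high").ranks
        n = len(values)
        assert r.sum() == pytest.approx(n * (n + 1) / 2)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-100, 100), min_size=2, max_size=40, unique=True),
        st.sampled_from(["better-is-high", "better-is-low"]),
    )
    def test_monotone(self, values, direction):
        s = pd.Series(values)
        r = rank_transform(s, direction).ranks
        order = s.sort_values(ascending=direction == "better-is-low").index
        assert r.loc[order].is_monotonic_increasing


class TestNetworkRankScore:
    def test_bounds_and_columns(self, small_data):
        table = network_rank_score(small_data.net, small_data.known)
        assert set(table.columns) >= {"c_d", "c_b", "c_spl", "rank_d", "rank_b", "rank_spl", "S_N"}
        assert table["S_N"].between(0, 1).all()

    def test_uniform_best_and_worst_limits(self):
        # star center: best degree, best betweenness, and (as the seed) best proximity
        net = build_network([[("h", f"l{i}") for i in range(1, 5)]])
        table = network_rank_score(net, GeneSet("s", ["h"]))
        assert table.loc["h", "S_N"] == 0.0
        # leaves tie on every attribute -> identical S_N strictly worse than the hub
        leaves = table.drop("h")
        assert leaves["S_N"].nunique() == 1 and (leaves["S_N"] > 0).all()

    def test_invariant_under_monotone_transform_of_attribute(self, small_data):
        # S_N depends on attribute order only: ranks of c_d equal ranks of exp(c_d)
        d = pd.Series(np.random.default_rng(3).integers(0, 10, 30), dtype=float)
        r1 = rank_transform(d, "better-is-high").ranks
        r2 = rank_transform(np.exp(d / 3.0), "better-is-high").ranks
        pd.testing.assert_series_equal(r1, r2)

    def test_hand_computed_average(self):
        # path a-b-c, seed {a}: verify S_N arithmetic on hand ranks
        net = build_network([[("a", "b"), ("b", "c")]])
        t = network_rank_score(net, GeneSet("s", ["a"]))
        # degree ranks: b=1, a=c=2.5 ; betweenness: b=1, a=c=2.5
        # c_spl: a=0 (rank 1), b=1 (rank 2), c=2 (rank 3)
        scaled = lambda r: (r - 1) / 2
        assert t.loc["a", "S_N"] == pytest.approx((scaled(2.5) + scaled(2.5) + scaled(1)) / 3)
        assert t.loc["b", "S_N"] == pytest.approx((scaled(1) + scaled(1) + scaled(2)) / 3)
        assert t.loc["c", "S_N"] == pytest.approx((scaled(2.5) + scaled(2.5) + scaled(3)) / 3)


def test_rescale_ranks_unit_interval():
    r = pd.Series([1.0, 2.0, 3.0, 4.0])
    assert rescale_ranks(r).tolist() == [0.0, 1 / 3, 2 / 3, 1.0]
    assert rescale_ranks(pd.Series([1.0])).tolist() == [0.5]
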