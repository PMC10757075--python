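"""Centrality measures: worked examples, oracle agreement, invariants."""

import networkx as nx
import pytest

import oracles
from conftest import (
    alternating_cycle,
    build_graph,
    edge_pairs,
    random_reaction_graph,
    reverse_graph,
)
from rxnnet.centrality import (
    category_degree_summary,
    closeness_centrality,
    degree_centrality,
    h_index,
    h_index_centrality,
    laplacian_centrality,
    leverage_centrality,
)


def nxg(edges):
    g = nx.MultiDiGraph()
    g.add_edges_from(edges)
    return g


class TestDegreeCentrality:
    def test_path(self, abc_path):
        assert degree_centrality(abc_path, "out").scores == {
            "a": 1.0, "r": 1.0, "c": 0.0}
        assert degree_centrality(abc_path, "in").scores == {
            "a": 0.0, "r": 1.0, "c": 1.0}
        assert degree_centrality(abc_path, "total").scores == {
            "a": 1.0, "r": 2.0, "c": 1.0}

    def test_parallel_edges_counted(self):
        g = build_graph(["a"], ["r"],
                        [("a", "r", "input"), ("a", "r", "catalyst")])
        assert degree_centrality(g, "out").scores["a"] == 2.0

    def test_isolated_node_scores_zero_in_all_directions(self):
        g = build_graph(["a"], [], [])
        for d in ("in", "out", "total"):
            assert degree_centrality(g, d).scores == {"a": 0.0}

    def test_invalid_direction(self):
        with pytest.raises(ValueError):
            degree_centrality(build_graph([], [], []), "sideways")


class TestHIndex:
    def test_out_star_center_scores_zero(self):
        # three leaves, all of out-degree 0: no neighbour has degree >= 1
        g = nxg([("v", "l1"), ("v", "l2"), ("v", "l3")])
        assert h_index_centrality(g, "out").scores["v"] == 0.0

    def test_alternating_four_cycle_all_one(self):
        g = alternating_cycle(2)
        assert set(h_index_centrality(g, "out").scores.values()) == {1.0}
        assert set(h_index_centrality(g, "in").scores.values()) == {1.0}

    def test_neighbor_degrees_3_3_2_give_2(self):
        # v -> a, b, c with out-degrees 3, 3, 2; sinks absorb the fan-out
        edges = [("v", "a"), ("v", "b"), ("v", "c")]
        edges += [("a", f"s{i}") for i in range(3)]
        edges += [("b", f"s{i}") for i in range(3, 6)]
        edges += [("c", f"s{i}") for i in range(6, 8)]
        assert h_index_centrality(nxg(edges), "out").scores["v"] == 2.0

    def test_h_index_helper_brute_force(self):
        for degs in ([], [0], [1], [3, 3, 2], [5, 4, 4, 2, 1], [2] * 7):
            best = 0
            for h in range(len(degs) + 1):
                if sum(1 for d in degs if d >= h) >= h:
                    best = h
            assert h_index(degs) == best

    def test_neighbor_degree_direction_switch(self):
        # a -> r; out-reading of the neighbour degree differs from total
        g = nxg([("a", "r"), ("x", "r")])
        same = h_index_centrality(g, "out").scores["a"]          # d+(r)=0
        total = h_index_centrality(g, "out",
                                   neighbor_degree_direction="total").scores["a"]
        assert (same, total) == (0.0, 1.0)


class TestLaplacian:
    def test_isolated(self):
        g = build_graph(["a"], [], [])
        assert laplacian_centrality(g, "out").scores == {"a": 0.0}

    def test_two_sink_neighbors(self):
        # d+(v)=2, both neighbours sinks: 4 + 2 + 0 = 6
        g = nxg([("v", "x"), ("v", "y")])
        assert laplacian_centrality(g, "out").scores["v"] == 6.0

    def test_directed_three_cycle_all_four(self):
        g = nxg([("x", "y"), ("y", "z"), ("z", "x")])
        assert set(laplacian_centrality(g, "out").scores.values()) == {4.0}
        assert set(laplacian_centrality(g, "in").scores.values()) == {4.0}

    def test_all_neighbors_sinks_identity(self):
        # LAPC(v) = d^2 + d when every out-neighbour is a sink
        g = nxg([("v", f"s{i}") for i in range(5)])
        assert laplacian_centrality(g, "out").scores["v"] == 30.0


class TestLeverage:
    def test_regular_cycle_zero_everywhere(self):
        g = alternating_cycle(3)
        assert set(leverage_centrality(g, "out").scores.values()) == {0.0}

    def test_two_sink_neighbors_score_one(self):
        g = nxg([("v", "x"), ("v", "y")])
        assert leverage_centrality(g, "out").scores["v"] == 1.0

    def test_sink_scores_zero_by_convention(self):
        g = nxg([("v", "x")])
        assert leverage_centrality(g, "out").scores["x"] == 0.0

    def test_scores_bounded(self):
        for seed in range(10):
            g = random_reaction_graph(seed)
            for d in ("in", "out"):
                assert all(
                    -1.0 <= s <= 1.0
                    for s in leverage_centrality(g, d).scores.values()
                )


class TestCloseness:
    def test_path_sink_scores_one(self, abc_path):
        # every node reaches c: 3 / (2 + 1 + 0)
        for mode in ("reachable", "strict"):
            assert closeness_centrality(abc_path, mode=mode).scores["c"] == 1.0

    def test_two_cycle_scores_two(self):
        g = alternating_cycle(1)  # e0 <-> r0
        scores = closeness_centrality(g).scores
        assert scores == {"e0": 2.0, "r0": 2.0}  # may exceed 1: numerator is n

    def test_unreached_node_scores_zero(self, abc_path):
        assert closeness_centrality(abc_path).scores["a"] == 0.0

    def test_strict_zeroes_partially_reachable_nodes(self, abc_path):
        strict = closeness_centrality(abc_path, mode="strict").scores
        assert strict == {"a": 0.0, "r": 0.0, "c": 1.0}

    def test_modes_agree_on_strongly_connected_graph(self):
        g = alternating_cycle(4)
        assert closeness_centrality(g, mode="reachable").scores == \
            closeness_centrality(g, mode="strict").scores

    def test_parallel_edges_irrelevant(self):
        g1 = build_graph(["a"], ["r"], [("a", "r", "input")])
        g2 = build_graph(["a"], ["r"],
                         [("a", "r", "input"), ("a", "r", "catalyst")])
        assert closeness_centrality(g1).scores == closeness_centrality(g2).scores

    def test_out_variant_is_in_variant_of_reverse(self):
        for seed in range(5):
            g = random_reaction_graph(seed)
            assert closeness_centrality(g, direction="out").scores == \
                closeness_centrality(reverse_graph(g), direction="in").scores


class TestCategorySummary:
    def test_single_category_mean(self):
        g = build_graph(
            ["a", "b"], ["r"],
            [("a", "r", "input"), ("a", "r", "catalyst"), ("b", "r", "input")],
        )
        df = category_degree_summary(g)
        row = df.set_index("schema_category").loc["SimpleEntity"]
        assert row.mean_out_degree == pytest.approx(1.5)  # degrees {2, 1}
        assert row.n_nodes == 2

    def test_empty_graph_empty_table(self):
        assert category_degree_summary(build_graph([], [], [])).empty

    def test_matches_brute_force_group_by(self):
        g = random_reaction_graph(17)
        df = category_degree_summary(g).set_index("schema_category")
        groups: dict[str, list[str]] = {}
        for r in g.nodes():
            groups.setdefault(r.schema_category, []).append(r.node_id)
        for cat, members in groups.items():
            mean_in = sum(g.in_degree(v) for v in members) / len(members)
            mean_out = sum(g.out_degree(v) for v in members) / len(members)
            assert df.loc[cat].mean_in_degree == pytest.approx(mean_in)
            assert df.loc[cat].mean_out_degree == pytest.approx(mean_out)


@pytest.mark.parametrize("seed", range(40))
def test_measures_match_naive_enumeration(seed):
    """Spot check against the literal-definition oracles (the full 200-graph
    sweep runs in the acceptance suite)."""
    g = random_reaction_graph(seed, max_side=12, max_edges=50)
    nodes, edges = g.node_ids(), edge_pairs(g)
    for d in ("in", "out"):
        assert degree_centrality(g, d).scores == pytest.approx(
            oracles.degree_scores(nodes, edges, d))
        assert h_index_centrality(g, d).scores == pytest.approx(
            oracles.h_index_scores(nodes, edges, d))
        assert laplacian_centrality(g, d).scores == pytest.approx(
            oracles.laplacian_scores(nodes, edges, d))
        assert leverage_centrality(g, d).scores == pytest.approx(
            oracles.leverage_scores(nodes, edges, d), abs=1e-9)
    for mode in ("reachable", "strict"):
        assert closeness_centrality(g, mode=mode).scores == pytest.approx(
            oracles.closeness_scores(nodes, edges, mode), abs=1e-9)


def test_h_index_bounded_by_degree_and_max_neighbor_degree():
    for seed in range(10):
        g = random_reaction_graph(seed)
        for d in ("in", "out"):
            hc = h_index_centrality(g, d).scores
            dc = degree_centrality(g, d).scores
            dmax = max(dc.values(), default=0)
            for v, h in hc.items():
                assert h <= dc[v]
                assert h <= dmax
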