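"""Compartment hierarchy pruning/re-linking and per-compartment statistics."""

import networkx as nx
import numpy as np
import pytest

from conftest import build_graph, entity, event
from rxnnet.compartments import (
    CELL,
    DUMMY_ROOT,
    EXTRACELLULAR,
    HierarchyError,
    build_hierarchy,
    compartment_stats_table,
    compartment_subgraph,
)
from rxnnet.connectivity import (
    strongly_connected_components,
    weakly_connected_components,
)
from rxnnet.fixtures import FixtureSpec, generate_fixture_db, generate_graph


def ontology(edges, extra_nodes=()):
    """obonet-style multigraph: edges child -> parent keyed by relation."""
    onto = nx.MultiDiGraph()
    onto.add_node(CELL, name="cell")
    onto.add_node(EXTRACELLULAR, name="extracellular region")
    for n in extra_nodes:
        onto.add_node(n, name=n)
    for child, parent, rel in edges:
        onto.add_edge(child, parent, key=rel)
    return onto


def graph_with_events_in(compartment_sets):
    ents, evts, edges = [], [], []
    for i, comps in enumerate(compartment_sets):
        evts.append(event(f"r{i}", compartments=comps))
    return build_graph(ents, evts, edges)


class TestPruning:
    def test_chain_relinks_to_lowest_retained_ancestor(self):
        # cell <- A <- B <- C with reactions only in A and C:
        # B is discarded and C re-linked to A
        onto = ontology([
            ("A", CELL, "part_of"),
            ("B", "A", "part_of"),
            ("C", "B", "part_of"),
        ])
        g = graph_with_events_in([{"A"}, {"C"}])
        h = build_hierarchy(onto, g)
        assert "B" not in h.compartments
        assert h.parents("C") == {"A"}
        assert h.parents("A") == {CELL}

    def test_diamond_with_both_parents_retained_keeps_both_links(self):
        onto = ontology([
            ("P1", CELL, "part_of"),
            ("P2", CELL, "part_of"),
            ("D", "P1", "part_of"),
            ("D", "P2", "is_a"),
        ])
        g = graph_with_events_in([{"P1"}, {"P2"}, {"D"}])
        h = build_hierarchy(onto, g)
        assert h.parents("D") == {"P1", "P2"}

    def test_diamond_with_discarded_middle_deduplicates_ancestor(self):
        # D -> B1 -> A and D -> B2 -> A; B1, B2 discarded: D linked to A once
        onto = ontology([
            ("A", CELL, "part_of"),
            ("B1", "A", "part_of"),
            ("B2", "A", "part_of"),
            ("D", "B1", "part_of"),
            ("D", "B2", "part_of"),
        ])
        g = graph_with_events_in([{"A"}, {"D"}])
        h = build_hierarchy(onto, g)
        assert h.parents("D") == {"A"}

    def test_no_op_pruning_when_every_compartment_has_reactions(self):
        onto = ontology([
            ("A", CELL, "part_of"),
            ("B", "A", "part_of"),
            ("X", EXTRACELLULAR, "part_of"),
        ])
        g = graph_with_events_in([{"A"}, {"B"}, {"X"}])
        h = build_hierarchy(onto, g)
        assert h.parents("B") == {"A"}
        assert h.parents("X") == {EXTRACELLULAR}
        assert h.children(DUMMY_ROOT) == {CELL, EXTRACELLULAR}
        assert h.retained == {"A", "B", "X"}

    def test_entities_alone_do_not_rescue_a_compartment(self):
        onto = ontology([("A", CELL, "part_of")])
        g = build_graph([entity("a", compartments={"A"})], [], [])
        h = build_hierarchy(onto, g)
        assert "A" not in h.compartments

    def test_unknown_accession_kept_as_leaf_under_root(self):
        onto = ontology([])
        g = graph_with_events_in([{"GO:9999999"}])
        with pytest.warns(UserWarning, match="GO:9999999"):
            h = build_hierarchy(onto, g)
        assert h.parents("GO:9999999") == {DUMMY_ROOT}
        assert "GO:9999999" in h.retained

    def test_ontology_cycle_rejected(self):
        onto = ontology([
            ("A", "B", "part_of"),
            ("B", "A", "part_of"),
        ])
        with pytest.raises(HierarchyError):
            build_hierarchy(onto, graph_with_events_in([{"A"}]))

    def test_every_retained_compartment_reaches_the_root(self):
        spec = FixtureSpec(n_events=40, n_entities=50, n_edges=100,
                           n_compartments=20, planted_cycle_sizes=(), seed=6)
        g = generate_graph(spec)
        from rxnnet.fixtures import generate_ontology

        h = build_hierarchy(generate_ontology(20, 5, 6), g)
        dag = h.dag()
        for comp in h.retained:
            assert nx.has_path(dag, comp, DUMMY_ROOT)

    def test_relation_filter_configurable(self):
        onto = ontology([("A", CELL, "occurs_in")])
        g = graph_with_events_in([{"A"}])
        with pytest.warns(UserWarning):  # occurs_in ignored by default
            h = build_hierarchy(onto, g)
        assert h.parents("A") == {DUMMY_ROOT}
        h2 = build_hierarchy(onto, g, relations=("occurs_in",))
        assert h2.parents("A") == {CELL}


class TestSubgraphs:
    def make_graph(self):
        return build_graph(
            [entity("a", compartments={"X"}), entity("c", compartments={"X"}),
             entity("k", compartments={"Y"})],
            [event("r", compartments={"X"})],
            [("a", "r", "input"), ("r", "c", "output"), ("k", "r", "catalyst")],
        )

    def test_induced_subgraph_drops_cross_compartment_edges(self):
        sub = compartment_subgraph(self.make_graph(), "X")
        assert set(sub.node_ids()) == {"a", "r", "c"}
        assert {(e.source, e.target) for e in sub.edges()} == {
            ("a", "r"), ("r", "c")}

    def test_compartment_labeling_every_node_is_identity(self):
        g = build_graph(
            [entity("a", compartments={"X"})],
            [event("r", compartments={"X"})],
            [("a", "r", "input")],
        )
        sub = compartment_subgraph(g, "X")
        assert sub == g

    def test_multi_label_node_in_both_subgraphs(self):
        g = build_graph([entity("a", compartments={"X", "Y"})], [], [])
        assert "a" in compartment_subgraph(g, "X")
        assert "a" in compartment_subgraph(g, "Y")

    def test_compartment_outside_hierarchy_rejected(self):
        onto = ontology([("X", CELL, "part_of")])
        g = self.make_graph()
        h = build_hierarchy(onto, g)
        with pytest.raises(KeyError):
            compartment_subgraph(g, "Z", h)

    def test_aggregate_descendants_unions_labels(self):
        onto = ontology([
            ("A", CELL, "part_of"),
            ("B", "A", "part_of"),
        ])
        g = build_graph(
            [entity("x", compartments={"B"})],
            [event("rA", compartments={"A"}), event("rB", compartments={"B"})],
            [],
        )
        h = build_hierarchy(onto, g)
        assert set(compartment_subgraph(g, "A", h).node_ids()) == {"rA"}
        agg = compartment_subgraph(g, "A", h, aggregate_descendants=True)
        assert set(agg.node_ids()) == {"rA", "rB", "x"}


class TestStatsTable:
    def test_single_compartment_matches_whole_graph_census(self):
        g = build_graph(
            [entity("a", compartments={"X"}), entity("c", compartments={"X"})],
            [event("r", compartments={"X"})],
            [("a", "r", "input"), ("r", "c", "output")],
        )
        onto = ontology([("X", CELL, "part_of")])
        table = compartment_stats_table(g, build_hierarchy(onto, g))
        row = table.set_index("compartment").loc["X"]
        assert row.n_nodes == g.n_nodes
        assert row.n_scc == len(strongly_connected_components(g))
        assert row.n_wcc == len(weakly_connected_components(g))

    def test_edgeless_compartment_counts_equal_nodes(self):
        g = build_graph(
            [entity(f"x{i}", compartments={"X"}) for i in range(3)],
            [event("r", compartments={"X"})],
            [],
        )
        onto = ontology([("X", CELL, "part_of")])
        table = compartment_stats_table(g, build_hierarchy(onto, g))
        row = table.set_index("compartment").loc["X"]
        assert (row.n_nodes, row.n_scc, row.n_wcc) == (4, 4, 4)

    def test_rows_satisfy_component_count_ordering(self):
        from rxnnet.fixtures import generate_ontology

        spec = FixtureSpec(n_events=60, n_entities=90, n_edges=250,
                           n_compartments=15, planted_cycle_sizes=(10,), seed=2)
        g = generate_graph(spec)
        h = build_hierarchy(generate_ontology(15, 5, 2), g)
        table = compartment_stats_table(g, h)
        assert len(table) > 0
        assert (table.n_wcc <= table.n_scc).all()
        assert (table.n_scc <= table.n_nodes).all()
        assert table.n_nodes.is_monotonic_decreasing

    def test_scc_counts_scale_linearly_on_acyclic_fixtures(self):
        """With no planted cycles and only entity->event edge types the
        fixture is acyclic, so per-compartment SCC counts regress on node
        counts with slope in (0.9, 1.0]."""
        from rxnnet.fixtures import generate_ontology

        spec = FixtureSpec(
            n_events=120, n_entities=180, n_edges=500,
            edge_type_mix={"input": 0.85, "catalyst": 0.15},
            n_compartments=25, planted_cycle_sizes=(), seed=3,
        )
        g = generate_graph(spec)
        h = build_hierarchy(generate_ontology(25, 5, 3), g)
        table = compartment_stats_table(g, h)
        slope = np.polyfit(table.n_nodes, table.n_scc, 1)[0]
        assert 0.9 < slope <= 1.0
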