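"""Shared test helpers: small hand-built graphs and seeded random ones."""

from __future__ import annotations

import numpy as np
import pytest

from rxnnet.model import (
    EVENT,
    PHYSICAL_ENTITY,
    NodeRecord,
    ReactionGraph,
)


def entity(node_id, compartments=(), category="SimpleEntity", name=""):
    return NodeRecord(
        node_id=node_id,
        node_class=PHYSICAL_ENTITY,
        display_name=name,
        compartments=frozenset(compartments),
        schema_category=category,
    )


def event(node_id, compartments=(), category="Reaction", name=""):
    return NodeRecord(
        node_id=node_id,
        node_class=EVENT,
        display_name=name,
        compartments=frozenset(compartments),
        schema_category=category,
    )


def build_graph(entities, events, edges, species="HSA"):
    """Assemble a graph from id lists and (source, target, type) triples."""
    g = ReactionGraph(species=species)
    for spec in entities:
        g.add_node(spec if isinstance(spec, NodeRecord) else entity(spec))
    for spec in events:
        g.add_node(spec if isinstance(spec, NodeRecord) else event(spec))
    for s, t, et in edges:
        g.add_edge(s, t, et)
    return g


def alternating_cycle(n_pairs, prefix=""):
    """Entity->event->entity directed cycle on 2*n_pairs nodes."""
    ents = [f"{prefix}e{i}" for i in range(n_pairs)]
    evts = [f"{prefix}r{i}" for i in range(n_pairs)]
    edges = []
    for i in range(n_pairs):
        edges.append((ents[i], evts[i], "input"))
        edges.append((evts[i], ents[(i + 1) % n_pairs], "output"))
    return build_graph(ents, evts, edges)


def random_reaction_graph(seed, max_side=25, max_edges=120):
    """A seeded random bipartite multigraph, independent of the generator
    module (edges drawn uniformly, not from the curated mix)."""
    rng = np.random.default_rng(seed)
    n_ent = int(rng.integers(1, max_side + 1))
    n_evt = int(rng.integers(1, max_side + 1))
    ents = [f"e{i}" for i in range(n_ent)]
    evts = [f"r{i}" for i in range(n_evt)]
    types = ["input", "output", "catalyst", "positive_regulation",
             "negative_regulation"]
    edges = []
    for _ in range(int(rng.integers(0, max_edges + 1))):
        t = types[rng.integers(len(types))]
        ent = ents[rng.integers(n_ent)]
        evt = evts[rng.integers(n_evt)]
        edges.append((evt, ent, t) if t == "output" else (ent, evt, t))
    return build_graph(ents, evts, edges)


def reverse_graph(g: ReactionGraph) -> ReactionGraph:
    """Edge-reversed graph: every edge flipped, node classes swapped so the
    typed-orientation invariants keep holding, edge types unchanged."""
    rev = ReactionGraph(species=g.species)
    for r in g.nodes():
        rev.add_node(NodeRecord(
            node_id=r.node_id,
            node_class=EVENT if r.node_class == PHYSICAL_ENTITY else PHYSICAL_ENTITY,
            display_name=r.display_name,
            schema_category=r.schema_category,
            compartments=r.compartments,
        ))
    for e in g.edges():
        rev.add_edge(e.target, e.source, e.edge_type)
    return rev


def edge_pairs(g: ReactionGraph):
    return [(e.source, e.target) for e in g.edges()]


@pytest.fixture
def abc_path():
    """a --input--> r --output--> c, the canonical 3-node path."""
    return build_graph(["a", "c"], ["r"], [("a", "r", "input"), ("r", "c", "output")])
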