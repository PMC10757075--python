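"""Seeded synthetic reaction networks and schema-dump fixtures.

This module generates toy reaction networks that follow the same schema as
the curated pathway store the importer targets, so every analysis module is
exercisable without a live database.  A fixture is controlled by
:class:`FixtureSpec` and can be materialized two ways:

* :func:`generate_graph` — the :class:`~rxnnet.model.ReactionGraph` directly;
* :func:`generate_fixture_db` — an on-disk labelled-property-graph dump
  (plus a matching OBO ontology) that
  :func:`rxnnet.importer.build_graph` imports back to the same graph.

Defaults are a 1:35 scale model of the human reaction network this package
is built to analyse: 1,000 nodes split 62.4% entities / 37.6% events, 1,507
typed edges drawn from the observed global edge-type mix (≈47.3% input,
37.9% output, 10.8% catalyst, 2.6% positive and 1.2% negative regulation),
and one planted alternating cycle covering 32.4% of the nodes, emulating
the giant strongly connected component.  Endpoints of random edges are
drawn with Zipf-like weights so degree distributions are heavy-tailed, as
in the curated network; everything is deterministic in ``seed``.

Cycles are planted explicitly: uniformly random bipartite digraphs at this
density essentially never produce a giant strongly connected component.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .model import EDGE_TYPES, EVENT, PHYSICAL_ENTITY, NodeRecord, ReactionGraph

__all__ = [
    "DEFAULT_EDGE_TYPE_MIX",
    "CELL_ACCESSION",
    "EXTRACELLULAR_ACCESSION",
    "FixtureSpecError",
    "FixtureSpec",
    "generate_ontology",
    "write_obo",
    "generate_graph",
    "generate_fixture_db",
]

#: Global edge-type mix of the curated human network (fractions of 52,654
#: edges: 24,937 input / 19,959 output / 5,703 catalyst / 1,393 positive /
#: 662 negative regulations), normalized.
DEFAULT_EDGE_TYPE_MIX: dict[str, float] = {
    "input": 24937 / 52654,
    "output": 19959 / 52654,
    "catalyst": 5703 / 52654,
    "positive_regulation": 1393 / 52654,
    "negative_regulation": 662 / 52654,
}

#: Ontology anchors for the two sides of the compartment hierarchy.
CELL_ACCESSION = "GO:0005623"
EXTRACELLULAR_ACCESSION = "GO:0005576"

_ZIPF_EXPONENT = 0.7  # heavy-tailed endpoint weights


class FixtureSpecError(ValueError):
    """The fixture specification is internally inconsistent."""


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic network.

    ``planted_cycle_sizes`` lists requested strongly-connected-component
    sizes; each is realized as an alternating entity→event→entity directed
    cycle, so odd sizes are rounded up to the next even number (a bipartite
    cycle has an even number of nodes) and the resulting component has at
    least the requested size.
    """

    n_events: int = 376
    n_entities: int = 624
    n_edges: int = 1507
    edge_type_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EDGE_TYPE_MIX)
    )
    n_compartments: int = 111
    compartment_dag_depth: int = 5
    planted_cycle_sizes: tuple[int, ...] = (324,)
    generic_event_fraction: float = 0.05
    n_foreign_events: int = 0
    species: str = "HSA"
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "edge_type_mix", dict(self.edge_type_mix))
        object.__setattr__(
            self, "planted_cycle_sizes", tuple(self.planted_cycle_sizes)
        )
        self.validate()

    def validate(self) -> None:
        for name in ("n_events", "n_entities", "n_edges", "n_compartments",
                     "compartment_dag_depth", "n_foreign_events"):
            if getattr(self, name) < 0:
                raise FixtureSpecError(f"{name} must be non-negative")
        unknown = set(self.edge_type_mix) - set(EDGE_TYPES)
        if unknown:
            raise FixtureSpecError(f"unknown edge types in mix: {sorted(unknown)}")
        probs = [self.edge_type_mix.get(t, 0.0) for t in EDGE_TYPES]
        if any(p < 0 or p > 1 for p in probs):
            raise FixtureSpecError("edge_type_mix probabilities must lie in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise FixtureSpecError(f"edge_type_mix must sum to 1, got {sum(probs)}")
        if self.n_edges > 0 and (self.n_events == 0 or self.n_entities == 0):
            raise FixtureSpecError("edges need both entity and event nodes")
        half_total = sum(self._cycle_halves())
        if half_total > self.n_entities or half_total > self.n_events:
            raise FixtureSpecError(
                "planted cycles need more entity/event nodes than the spec provides"
            )
        if not 0.0 <= self.generic_event_fraction <= 1.0:
            raise FixtureSpecError("generic_event_fraction must lie in [0, 1]")

    def _cycle_halves(self) -> list[int]:
        """Entities (= events) consumed by each planted cycle."""
        return [math.ceil(k / 2) for k in self.planted_cycle_sizes]

    @property
    def probs(self) -> np.ndarray:
        return np.array([self.edge_type_mix.get(t, 0.0) for t in EDGE_TYPES])


# ---------------------------------------------------------------------------
# Ontology
# ---------------------------------------------------------------------------

def generate_ontology(
    n_terms: int, depth: int, seed: int = 0
) -> nx.MultiDiGraph:
    """A synthetic cell-compartment ontology fragment.

    Returns a multigraph in the convention OBO readers use: one node per
    term, edges child → parent keyed by the relation (``is_a`` or
    ``part_of``).  Two real anchors — the cell and the extracellular region
    — sit at the top with no parents; every synthetic term reaches exactly
    one of them.  About 15% of non-top terms get a second parent, so the
    result is a DAG rather than a forest, as real compartment annotation is.
    """
    rng = np.random.default_rng([seed, 0xC0])
    onto = nx.MultiDiGraph()
    onto.add_node(CELL_ACCESSION, name="cell", namespace="cellular_component")
    onto.add_node(
        EXTRACELLULAR_ACCESSION,
        name="extracellular region",
        namespace="cellular_component",
    )
    depth = max(depth, 1)
    terms = [f"GO:88{i:05d}" for i in range(n_terms)]
    # Spread terms over levels; level 0 hangs off the anchors.
    levels: list[list[str]] = [[] for _ in range(depth)]
    for i, t in enumerate(terms):
        levels[i % depth].append(t)
    # Remove trailing empty levels, keep level order stable in term index.
    levels = [lv for lv in levels if lv]
    for li, level in enumerate(levels):
        for t in level:
            onto.add_node(
                t, name=f"synthetic compartment {t[3:]}",
                namespace="cellular_component",
            )
            if li == 0:
                anchor = (
                    EXTRACELLULAR_ACCESSION
                    if rng.random() < 0.1
                    else CELL_ACCESSION
                )
                onto.add_edge(t, anchor, key="part_of")
            else:
                parents = list(levels[li - 1])
                first = parents[rng.integers(len(parents))]
                rel = "is_a" if rng.random() < 0.3 else "part_of"
                onto.add_edge(t, first, key=rel)
                if len(parents) > 1 and rng.random() < 0.15:
                    second = first
                    while second == first:
                        second = parents[rng.integers(len(parents))]
                    onto.add_edge(t, second, key="part_of")
    return onto


def write_obo(onto: nx.MultiDiGraph, path: str | Path) -> None:
    """Write an ontology graph as a minimal OBO 1.2 document."""
    lines = ["format-version: 1.2", "ontology: synthetic-cellular-component", ""]
    for term in sorted(onto.nodes):
        data = onto.nodes[term]
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {data.get('name', term)}")
        lines.append(f"namespace: {data.get('namespace', 'cellular_component')}")
        for _, parent, rel in sorted(onto.out_edges(term, keys=True)):
            if rel == "is_a":
                lines.append(f"is_a: {parent} ! {onto.nodes[parent].get('name', '')}")
            else:
                lines.append(
                    f"relationship: {rel} {parent} "
                    f"! {onto.nodes[parent].get('name', '')}"
                )
        lines.append("")
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# Network generation
# ---------------------------------------------------------------------------

_ENTITY_CATEGORIES = (
    "SimpleEntity",
    "Complex",
    "EntityWithAccessionedSequence",
    "DefinedSet",
    "CandidateSet",
)
_EVENT_CATEGORIES = ("Reaction", "BlackBoxEvent", "Polymerisation", "Depolymerisation")


@dataclass
class _FixtureData:
    """Shared intermediate: node records, typed edges, dump extras."""

    spec: FixtureSpec
    entities: list[NodeRecord]
    events: list[NodeRecord]
    edges: list[tuple[str, str, str]]  # (source, target, edge_type)
    foreign_events: list[NodeRecord]
    ontology: nx.MultiDiGraph


def _zipf_weights(n: int, rng: np.random.Generator) -> np.ndarray:
    ranks = rng.permutation(n) + 1
    w = ranks.astype(float) ** (-_ZIPF_EXPONENT)
    return w / w.sum()


def _build_fixture(spec: FixtureSpec) -> _FixtureData:
    rng = np.random.default_rng([spec.seed, 0x01])
    onto = generate_ontology(
        spec.n_compartments, spec.compartment_dag_depth, spec.seed
    )
    terms = sorted(t for t in onto.nodes
                   if t not in (CELL_ACCESSION, EXTRACELLULAR_ACCESSION))

    def draw_compartments() -> frozenset[str]:
        if not terms:
            return frozenset()
        labels = {terms[rng.integers(len(terms))]}
        if rng.random() < 0.1:
            labels.add(terms[rng.integers(len(terms))])
        return frozenset(labels)

    entity_ids = []
    for i in range(spec.n_entities):
        slug = "ALL" if rng.random() < 0.1 else spec.species
        entity_ids.append(f"R-{slug}-2{i:06d}")
    event_ids = []
    for j in range(spec.n_events):
        if rng.random() < spec.generic_event_fraction:
            slug = "ALL" if rng.random() < 0.5 else "NUL"
        else:
            slug = spec.species
        event_ids.append(f"R-{slug}-1{j:06d}")

    entities = [
        NodeRecord(
            node_id=eid,
            node_class=PHYSICAL_ENTITY,
            display_name=f"entity {i}",
            compartments=draw_compartments(),
            schema_category=_ENTITY_CATEGORIES[
                rng.integers(len(_ENTITY_CATEGORIES))
            ],
        )
        for i, eid in enumerate(entity_ids)
    ]
    events = [
        NodeRecord(
            node_id=rid,
            node_class=EVENT,
            display_name=f"reaction {j}",
            compartments=draw_compartments(),
            schema_category=_EVENT_CATEGORIES[rng.integers(len(_EVENT_CATEGORIES))],
        )
        for j, rid in enumerate(event_ids)
    ]

    edges: list[tuple[str, str, str]] = []

    # Planted alternating cycles: dedicated nodes from the front of each pool.
    ent_cursor = evt_cursor = 0
    for half in spec._cycle_halves():
        cyc_entities = entity_ids[ent_cursor:ent_cursor + half]
        cyc_events = event_ids[evt_cursor:evt_cursor + half]
        ent_cursor += half
        evt_cursor += half
        for idx in range(half):
            edges.append((cyc_entities[idx], cyc_events[idx], "input"))
            edges.append(
                (cyc_events[idx], cyc_entities[(idx + 1) % half], "output")
            )

    # Random edges: types i.i.d. from the mix, heavy-tailed endpoints.  The
    # first pass cycles through every entity so each one is attached to at
    # least one event whenever n_edges >= n_entities.
    if spec.n_edges > 0:
        types = [str(t) for t in rng.choice(EDGE_TYPES, size=spec.n_edges, p=spec.probs)]
        ent_w = _zipf_weights(spec.n_entities, rng)
        evt_w = _zipf_weights(spec.n_events, rng)
        coverage = rng.permutation(spec.n_entities)
        ent_draws = rng.choice(spec.n_entities, size=spec.n_edges, p=ent_w)
        evt_draws = rng.choice(spec.n_events, size=spec.n_edges, p=evt_w)
        for j, t in enumerate(types):
            ei = coverage[j] if j < spec.n_entities else ent_draws[j]
            ent, evt = entity_ids[ei], event_ids[evt_draws[j]]
            if t == "output":
                edges.append((evt, ent, t))
            else:
                edges.append((ent, evt, t))

    foreign = [
        NodeRecord(
            node_id=f"R-MMU-9{j:06d}",
            node_class=EVENT,
            display_name=f"foreign reaction {j}",
            compartments=draw_compartments(),
            schema_category="Reaction",
        )
        for j in range(spec.n_foreign_events)
    ]
    return _FixtureData(spec, entities, events, edges, foreign, onto)


def generate_graph(spec: FixtureSpec) -> ReactionGraph:
    """Materialize the synthetic network as a reaction graph.

    Identical specs (including seed) produce identical graphs; serialized
    with :func:`rxnnet.importer.save_graph` they are byte-identical.
    """
    data = _build_fixture(spec)
    graph = ReactionGraph(species=spec.species)
    for record in data.entities + data.events:
        graph.add_node(record)
    for src, dst, t in data.edges:
        graph.add_edge(src, dst, t)
    return graph


# ---------------------------------------------------------------------------
# Schema dump
# ---------------------------------------------------------------------------

def _fixture_dump(data: _FixtureData) -> dict:
    spec = data.spec
    nodes: list[dict] = []
    rels: list[dict] = []
    seen_terms: set[str] = set()

    def term_node(acc: str) -> str:
        nid = f"go::{acc}"
        if acc not in seen_terms:
            seen_terms.add(acc)
            nodes.append({
                "id": nid,
                "labels": ["GO_CellularComponent"],
                "properties": {
                    "accession": acc.removeprefix("GO:"),
                    "displayName": data.ontology.nodes[acc].get("name", acc)
                    if acc in data.ontology else acc,
                },
            })
        return nid

    nodes.append({
        "id": f"species::{spec.species}",
        "labels": ["Species"],
        "properties": {"code": spec.species, "displayName": spec.species},
    })
    if data.foreign_events:
        nodes.append({
            "id": "species::MMU",
            "labels": ["Species"],
            "properties": {"code": "MMU", "displayName": "MMU"},
        })

    for rec in data.entities:
        nodes.append({
            "id": rec.node_id,
            "labels": ["PhysicalEntity", rec.schema_category],
            "properties": {
                "stId": rec.node_id,
                "displayName": rec.display_name,
                "schemaClass": rec.schema_category,
            },
        })
        for acc in sorted(rec.compartments):
            rels.append({"type": "compartment", "start": rec.node_id,
                         "end": term_node(acc)})

    for rec in data.events + data.foreign_events:
        nodes.append({
            "id": rec.node_id,
            "labels": ["Event", "ReactionLikeEvent", rec.schema_category],
            "properties": {
                "stId": rec.node_id,
                "displayName": rec.display_name,
                "schemaClass": rec.schema_category,
            },
        })
        for acc in sorted(rec.compartments):
            rels.append({"type": "compartment", "start": rec.node_id,
                         "end": term_node(acc)})
        if rec in data.foreign_events:
            rels.append({"type": "species", "start": rec.node_id,
                         "end": "species::MMU"})
        elif not rec.is_generic:
            rels.append({"type": "species", "start": rec.node_id,
                         "end": f"species::{spec.species}"})
        # Generic events carry no species relationship: they are retained by
        # the identifier pattern alone, as in the source schema.

    aux = 0
    for src, dst, t in data.edges:
        if t == "input":
            rels.append({"type": "input", "start": dst, "end": src})
        elif t == "output":
            rels.append({"type": "output", "start": src, "end": dst})
        elif t == "catalyst":
            ca_id = f"ca::{aux}"
            aux += 1
            nodes.append({"id": ca_id, "labels": ["CatalystActivity"],
                          "properties": {}})
            rels.append({"type": "catalystActivity", "start": dst, "end": ca_id})
            rels.append({"type": "physicalEntity", "start": ca_id, "end": src})
        else:
            label = ("PositiveRegulation" if t == "positive_regulation"
                     else "NegativeRegulation")
            reg_id = f"reg::{aux}"
            aux += 1
            nodes.append({"id": reg_id, "labels": ["Regulation", label],
                          "properties": {}})
            rels.append({"type": "regulatedBy", "start": dst, "end": reg_id})
            rels.append({"type": "regulator", "start": reg_id, "end": src})

    return {"schema_version": 73, "nodes": nodes, "relationships": rels}


def generate_fixture_db(spec: FixtureSpec, path: str | Path) -> Path:
    """Write the fixture as an importable schema dump.

    Creates ``<path>/db.json`` (the labelled-property-graph dump) and
    ``<path>/go.obo`` (the matching compartment ontology); returns the dump
    path.  Importing the dump with
    :func:`rxnnet.importer.build_graph` reproduces
    :func:`generate_graph` exactly whenever every entity is attached to an
    event (guaranteed for ``n_edges >= n_entities``); entities with no
    relationships are present in the dump but, per the extraction contract,
    are not imported.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    data = _build_fixture(spec)
    dump = _fixture_dump(data)
    db_path = path / "db.json"
    with open(db_path, "w") as fh:
        json.dump(dump, fh, indent=1, sort_keys=True)
        fh.write("\n")
    write_obo(data.ontology, path / "go.obo")
    return db_path
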