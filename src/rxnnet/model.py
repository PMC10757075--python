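"""Bipartite directed multigraph model of a biochemical reaction network.

A reaction network is modelled as a bipartite directed multigraph with two
node classes:

* **physical entities** — molecular species (simple molecules, proteins,
  complexes, ...).  An occurrence of the same molecule in a different cell
  compartment is a different node; the curated stable identifier already
  disambiguates this.
* **events** — biochemical reactions (including black-box placeholder
  events) consuming inputs and producing outputs.

Edges are typed.  ``input``, ``catalyst``, ``positive_regulation`` and
``negative_regulation`` edges run from an entity into an event; ``output``
edges run from an event to an entity.  Parallel edges are permitted (the
same molecule may, e.g., be both an input and a catalyst of one reaction),
which is what makes the structure a multigraph; self-loops are impossible
by bipartiteness.

Degree counts *edges* (so parallel edges count separately) while
neighbourhoods are *sets of distinct nodes*; the centrality formulas in
:mod:`rxnnet.centrality` need both semantics side by side.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx

__all__ = [
    "EDGE_TYPES",
    "ENTITY_TO_EVENT_TYPES",
    "GENERIC_EVENT_PATTERN",
    "GraphError",
    "DuplicateNodeError",
    "UnknownNodeError",
    "InvalidEdgeError",
    "NodeRecord",
    "EdgeRecord",
    "ReactionCompounds",
    "ReactionGraph",
]

#: Edge vocabulary, in canonical order.
EDGE_TYPES: tuple[str, ...] = (
    "input",
    "output",
    "catalyst",
    "positive_regulation",
    "negative_regulation",
)

#: Edge types oriented entity -> event.  ``output`` is the only event -> entity type.
ENTITY_TO_EVENT_TYPES = frozenset(
    {"input", "catalyst", "positive_regulation", "negative_regulation"}
)

#: Stable identifiers of species-independent ("generic") events.  Generic
#: reactions are not tied to a single species and carry ALL/NUL species slugs.
GENERIC_EVENT_PATTERN = re.compile(r"R-(ALL|NUL)-.*")

PHYSICAL_ENTITY = "physical_entity"
EVENT = "event"
_NODE_CLASSES = (PHYSICAL_ENTITY, EVENT)


class GraphError(Exception):
    """Base class for reaction-graph contract violations."""


class DuplicateNodeError(GraphError):
    """A node with this stable identifier is already present."""


class UnknownNodeError(GraphError, KeyError):
    """Lookup of a stable identifier that is not in the graph."""


class InvalidEdgeError(GraphError):
    """Edge violates the bipartite orientation contract or references a bad type."""


@dataclass(frozen=True)
class NodeRecord:
    """One node of the reaction graph.

    Parameters
    ----------
    node_id:
        Curated stable identifier, e.g. ``"R-HSA-123456"`` or ``"R-ALL-29370"``.
    node_class:
        ``"physical_entity"`` or ``"event"``.
    display_name:
        Human-readable label.
    compartments:
        Ontology accessions of the cell compartments annotating this node.
        May be empty or hold several accessions.
    schema_category:
        Free-text schema class label (``"SimpleEntity"``, ``"Complex"``,
        ``"Reaction"``, ``"BlackBoxEvent"``, ...) used for per-category
        summaries.  Deliberately an opaque string, not an enum, so the
        summaries survive upstream schema evolution.
    is_generic:
        True iff the node is an *event* whose identifier matches the
        species-independent pattern ``R-(ALL|NUL)-.*``.  Computed from the
        identifier when not supplied.  Entities may carry ALL-slug ids
        (e.g. small molecules shared across species) without being generic
        reactions.
    """

    node_id: str
    node_class: str
    display_name: str = ""
    compartments: frozenset[str] = field(default_factory=frozenset)
    schema_category: str = ""
    is_generic: bool | None = None

    def __post_init__(self) -> None:
        if self.node_class not in _NODE_CLASSES:
            raise GraphError(
                f"invalid node_class {self.node_class!r} for {self.node_id!r}; "
                f"expected one of {_NODE_CLASSES}"
            )
        object.__setattr__(self, "compartments", frozenset(self.compartments))
        if self.is_generic is None:
            generic = (
                self.node_class == EVENT
                and GENERIC_EVENT_PATTERN.fullmatch(self.node_id) is not None
            )
            object.__setattr__(self, "is_generic", generic)
        elif self.is_generic and self.node_class != EVENT:
            raise GraphError(
                f"{self.node_id!r}: only event nodes can be generic reactions"
            )


@dataclass(frozen=True)
class EdgeRecord:
    """One typed, possibly parallel, directed edge.

    ``edge_key`` disambiguates parallel edges sharing (source, target);
    (source, target, edge_key) is unique within a graph.
    """

    source: str
    target: str
    edge_type: str
    edge_key: int = 0

    def __post_init__(self) -> None:
        if self.edge_type not in EDGE_TYPES:
            raise InvalidEdgeError(
                f"unknown edge_type {self.edge_type!r}; expected one of {EDGE_TYPES}"
            )


@dataclass(frozen=True)
class ReactionCompounds:
    """Entities adjacent to one event, grouped by edge type."""

    inputs: frozenset[str]
    outputs: frozenset[str]
    catalysts: frozenset[str]
    positive_regulators: frozenset[str]
    negative_regulators: frozenset[str]


def _required_orientation(edge_type: str) -> tuple[str, str]:
    """(source class, target class) demanded by the edge type."""
    if edge_type in ENTITY_TO_EVENT_TYPES:
        return PHYSICAL_ENTITY, EVENT
    return EVENT, PHYSICAL_ENTITY


class ReactionGraph:
    """A species-tagged bipartite directed multigraph of entities and events.

    Thin wrapper over :class:`networkx.MultiDiGraph` enforcing the model's
    invariants at insertion time: unique stable ids, typed edges with the
    orientation forced by their type, bipartiteness.  The underlying
    multigraph is exposed read-only as :attr:`nx_graph` so that any generic
    graph algorithm can be applied directly.
    """

    def __init__(self, species: str = "") -> None:
        self._g = nx.MultiDiGraph()
        self.species = species

    # -- basic accessors ---------------------------------------------------

    @property
    def nx_graph(self) -> nx.MultiDiGraph:
        """The underlying multigraph (treat as read-only)."""
        return self._g

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._g

    def __len__(self) -> int:
        return self.n_nodes

    def node(self, node_id: str) -> NodeRecord:
        try:
            data = self._g.nodes[node_id]
        except KeyError:
            raise UnknownNodeError(node_id) from None
        return NodeRecord(node_id=node_id, **data)

    def nodes(self) -> Iterator[NodeRecord]:
        for node_id in self._g.nodes:
            yield self.node(node_id)

    def node_ids(self) -> list[str]:
        return list(self._g.nodes)

    def entity_ids(self) -> list[str]:
        return [n for n, c in self._g.nodes(data="node_class") if c == PHYSICAL_ENTITY]

    def event_ids(self) -> list[str]:
        return [n for n, c in self._g.nodes(data="node_class") if c == EVENT]

    def node_class(self, node_id: str) -> str:
        try:
            return self._g.nodes[node_id]["node_class"]
        except KeyError:
            raise UnknownNodeError(node_id) from None

    def edges(self) -> Iterator[EdgeRecord]:
        for u, v, k, t in self._g.edges(keys=True, data="edge_type"):
            yield EdgeRecord(source=u, target=v, edge_type=t, edge_key=k)

    # -- construction ------------------------------------------------------

    def add_node(self, record: NodeRecord) -> None:
        """Insert a node; rejects duplicate stable identifiers."""
        if record.node_id in self._g:
            raise DuplicateNodeError(record.node_id)
        self._g.add_node(
            record.node_id,
            node_class=record.node_class,
            display_name=record.display_name,
            compartments=frozenset(record.compartments),
            schema_category=record.schema_category,
            is_generic=record.is_generic,
        )

    def add_edge(
        self, source: str, target: str, edge_type: str, edge_key: int | None = None
    ) -> int:
        """Insert a typed edge, returning its key.

        Both endpoints must already exist and their classes must match the
        orientation the edge type demands.  A colliding or absent
        ``edge_key`` is replaced with a fresh one, preserving multigraph
        semantics (parallel edges are never merged or overwritten).
        """
        if edge_type not in EDGE_TYPES:
            raise InvalidEdgeError(
                f"unknown edge_type {edge_type!r}; expected one of {EDGE_TYPES}"
            )
        for endpoint in (source, target):
            if endpoint not in self._g:
                raise UnknownNodeError(endpoint)
        want_src, want_dst = _required_orientation(edge_type)
        got_src = self._g.nodes[source]["node_class"]
        got_dst = self._g.nodes[target]["node_class"]
        if (got_src, got_dst) != (want_src, want_dst):
            raise InvalidEdgeError(
                f"{edge_type} edge must run {want_src} -> {want_dst}, "
                f"got {got_src} ({source!r}) -> {got_dst} ({target!r})"
            )
        if edge_key is not None and self._g.has_edge(source, target, key=edge_key):
            edge_key = None  # collision: allocate a fresh key instead of overwriting
        key = self._g.add_edge(source, target, key=edge_key, edge_type=edge_type)
        return key

    def add_edge_record(self, edge: EdgeRecord) -> int:
        return self.add_edge(edge.source, edge.target, edge.edge_type, edge.edge_key)

    # -- degrees and neighbourhoods ---------------------------------------

    def _check_node(self, node_id: str) -> None:
        if node_id not in self._g:
            raise UnknownNodeError(node_id)

    def in_degree(self, node_id: str, edge_types: Iterable[str] | None = None) -> int:
        """Number of incoming edges (parallel edges counted separately).

        ``edge_types`` optionally restricts the count to a subset of the
        edge vocabulary; by default every edge type contributes.
        """
        self._check_node(node_id)
        if edge_types is None:
            return self._g.in_degree(node_id)
        allowed = frozenset(edge_types)
        return sum(
            1 for *_ , t in self._g.in_edges(node_id, data="edge_type") if t in allowed
        )

    def out_degree(self, node_id: str, edge_types: Iterable[str] | None = None) -> int:
        """Number of outgoing edges (parallel edges counted separately)."""
        self._check_node(node_id)
        if edge_types is None:
            return self._g.out_degree(node_id)
        allowed = frozenset(edge_types)
        return sum(
            1 for *_ , t in self._g.out_edges(node_id, data="edge_type") if t in allowed
        )

    def degree(self, node_id: str, edge_types: Iterable[str] | None = None) -> int:
        return self.in_degree(node_id, edge_types) + self.out_degree(node_id, edge_types)

    def in_neighbors(
        self, node_id: str, edge_types: Iterable[str] | None = None
    ) -> set[str]:
        """Distinct predecessors of a node (edge multiplicity ignored)."""
        self._check_node(node_id)
        if edge_types is None:
            return set(self._g.predecessors(node_id))
        allowed = frozenset(edge_types)
        return {
            u for u, _, t in self._g.in_edges(node_id, data="edge_type") if t in allowed
        }

    def out_neighbors(
        self, node_id: str, edge_types: Iterable[str] | None = None
    ) -> set[str]:
        """Distinct successors of a node (edge multiplicity ignored)."""
        self._check_node(node_id)
        if edge_types is None:
            return set(self._g.successors(node_id))
        allowed = frozenset(edge_types)
        return {
            v for _, v, t in self._g.out_edges(node_id, data="edge_type") if t in allowed
        }

    def neighbors(self, node_id: str, edge_types: Iterable[str] | None = None) -> set[str]:
        return self.in_neighbors(node_id, edge_types) | self.out_neighbors(
            node_id, edge_types
        )

    # -- domain queries ----------------------------------------------------

    def reaction_compounds(self, event_id: str) -> ReactionCompounds:
        """Entities participating in an event, grouped by role.

        An entity related to the event through several edge types (e.g.
        both input and catalyst) appears in each corresponding group.
        """
        self._check_node(event_id)
        if self._g.nodes[event_id]["node_class"] != EVENT:
            raise InvalidEdgeError(
                f"{event_id!r} is a physical entity, not an event"
            )
        groups: dict[str, set[str]] = {t: set() for t in EDGE_TYPES}
        for u, _, t in self._g.in_edges(event_id, data="edge_type"):
            groups[t].add(u)
        for _, v, t in self._g.out_edges(event_id, data="edge_type"):
            groups[t].add(v)
        return ReactionCompounds(
            inputs=frozenset(groups["input"]),
            outputs=frozenset(groups["output"]),
            catalysts=frozenset(groups["catalyst"]),
            positive_regulators=frozenset(groups["positive_regulation"]),
            negative_regulators=frozenset(groups["negative_regulation"]),
        )

    def edge_type_counts(self) -> dict[str, int]:
        """Number of edges of each type (a partition of the edge set)."""
        counts = {t: 0 for t in EDGE_TYPES}
        for *_, t in self._g.edges(data="edge_type"):
            counts[t] += 1
        return counts

    def validate(self) -> None:
        """Re-check every structural invariant; raises on violation."""
        for u, v, t in self._g.edges(data="edge_type"):
            want = _required_orientation(t)
            got = (self._g.nodes[u]["node_class"], self._g.nodes[v]["node_class"])
            if got != want:
                raise InvalidEdgeError(f"edge {u}->{v} ({t}) violates bipartiteness")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        """Node-link dictionary with all record fields; JSON-serializable."""
        return {
            "species": self.species,
            "nodes": [
                {
                    "node_id": r.node_id,
                    "node_class": r.node_class,
                    "display_name": r.display_name,
                    "compartments": sorted(r.compartments),
                    "schema_category": r.schema_category,
                    "is_generic": r.is_generic,
                }
                for r in self.nodes()
            ],
            "edges": [
                {
                    "source": e.source,
                    "target": e.target,
                    "edge_type": e.edge_type,
                    "edge_key": e.edge_key,
                }
                for e in self.edges()
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ReactionGraph":
        graph = cls(species=data.get("species", ""))
        for nd in data["nodes"]:
            graph.add_node(
                NodeRecord(
                    node_id=nd["node_id"],
                    node_class=nd["node_class"],
                    display_name=nd.get("display_name", ""),
                    compartments=frozenset(nd.get("compartments", ())),
                    schema_category=nd.get("schema_category", ""),
                    is_generic=nd.get("is_generic"),
                )
            )
        for ed in data["edges"]:
            graph.add_edge(
                ed["source"], ed["target"], ed["edge_type"], ed.get("edge_key")
            )
        return graph

    def __eq__(self, other: object) -> bool:
        """Equality on (species, node records, typed-edge multiset).

        Edge keys are excluded: they only disambiguate parallel edges and
        may be relabelled within a parallel bundle by serialization.
        """
        if not isinstance(other, ReactionGraph):
            return NotImplemented
        if self.species != other.species:
            return False
        if set(self.nodes()) != set(other.nodes()):
            return False
        return self._typed_edge_multiset() == other._typed_edge_multiset()

    def _typed_edge_multiset(self) -> dict[tuple[str, str, str], int]:
        out: dict[tuple[str, str, str], int] = {}
        for u, v, t in self._g.edges(data="edge_type"):
            out[(u, v, t)] = out.get((u, v, t), 0) + 1
        return out
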