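"""Build a :class:`~rxnnet.model.ReactionGraph` from a curated pathway store.

The upstream pathway knowledge base ships as a labelled property graph.  The
extraction implemented here targets, for a chosen species:

* every ``ReactionLikeEvent`` whose ``species`` relationship points at the
  species of interest, **or** whose stable identifier matches the
  species-independent pattern ``R-(ALL|NUL)-.*`` (generic reactions shared
  by all species);
* every ``PhysicalEntity`` reached from a retained event through an
  ``input`` or ``output`` relationship;
* regulator entities reached through ``regulatedBy`` -> Regulation ->
  ``regulator`` chains, with the edge signed positive or negative by the
  Regulation node's class (``PositiveRegulation`` vs ``NegativeRegulation``);
* catalyst entities reached through ``catalystActivity`` -> CatalystActivity
  -> ``physicalEntity`` chains.

``referenceEntity`` relationships are consulted only for entity identity
metadata (reference display names); they never create graph edges.

The query layer is written against :class:`SchemaStore`, a minimal
label/relationship table interface.  The package ships
:class:`JsonSchemaStore`, which reads a plain-JSON dump of such a store (the
format :func:`rxnnet.fixtures.generate_fixture_db` writes), so the importer
is fully exercisable offline; a live graph-database client can be plugged in
by implementing the same three-method interface.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Protocol

import networkx as nx

from .model import EVENT, PHYSICAL_ENTITY, EdgeRecord, NodeRecord, ReactionGraph

__all__ = [
    "ImportConfig",
    "ImportError_",
    "ParseError",
    "SchemaStore",
    "JsonSchemaStore",
    "build_graph",
    "save_graph",
    "load_graph",
]

#: Schema labels the importer requires.
_REQUIRED_LABELS = ("ReactionLikeEvent", "PhysicalEntity")

#: The pinned upstream schema version the relationship vocabulary targets.
PINNED_SCHEMA_VERSION = 73


class ImportError_(Exception):
    """Store is unreachable or does not conform to the expected schema."""


class ParseError(Exception):
    """A serialized graph file is malformed; message carries element context."""


@dataclass(frozen=True)
class ImportConfig:
    """Parameters of one extraction run.

    ``generic_reaction_pattern`` must compile; it defaults to the
    species-independent identifier pattern.
    """

    species_code: str = "HSA"
    db_uri: str = ""
    credentials: Any = None
    generic_reaction_pattern: str = r"R-(ALL|NUL)-.*"

    def __post_init__(self) -> None:
        re.compile(self.generic_reaction_pattern)  # raises re.error if invalid

    @property
    def pattern(self) -> re.Pattern:
        return re.compile(self.generic_reaction_pattern)


class SchemaStore(Protocol):
    """Read-only view of a labelled property graph.

    ``node_ids_with_label`` lists node ids carrying a label;
    ``node_properties`` returns a property mapping (must include ``stId``
    for curated nodes); ``related`` follows relationships of one type from
    a node, in insertion order.
    """

    def node_ids_with_label(self, label: str) -> list[str]: ...

    def node_properties(self, node_id: str) -> dict: ...

    def labels(self, node_id: str) -> frozenset[str]: ...

    def related(self, node_id: str, rel_type: str) -> list[str]: ...


@dataclass
class JsonSchemaStore:
    """Schema store backed by a JSON dump.

    Dump layout::

        {"schema_version": 73,
         "nodes": [{"id": ..., "labels": [...], "properties": {...}}, ...],
         "relationships": [{"type": ..., "start": ..., "end": ...}, ...]}
    """

    nodes: dict[str, dict]
    rels: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    schema_version: int | None = None

    @classmethod
    def from_dump(cls, dump: dict) -> "JsonSchemaStore":
        nodes = {n["id"]: n for n in dump["nodes"]}
        store = cls(nodes=nodes, schema_version=dump.get("schema_version"))
        for r in dump["relationships"]:
            if r["start"] not in nodes or r["end"] not in nodes:
                raise ImportError_(
                    f"relationship {r['type']!r} references unknown node "
                    f"{r['start']!r} or {r['end']!r}"
                )
            store.rels.setdefault((r["start"], r["type"]), []).append(r["end"])
        return store

    @classmethod
    def from_json(cls, path: str | Path) -> "JsonSchemaStore":
        path = Path(path)
        if not path.exists():
            raise ImportError_(f"store not reachable: {path} does not exist")
        with open(path) as fh:
            try:
                dump = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ImportError_(f"{path}: not a valid store dump: {exc}") from exc
        return cls.from_dump(dump)

    def node_ids_with_label(self, label: str) -> list[str]:
        return [nid for nid, n in self.nodes.items() if label in n["labels"]]

    def node_properties(self, node_id: str) -> dict:
        return self.nodes[node_id].get("properties", {})

    def labels(self, node_id: str) -> frozenset[str]:
        return frozenset(self.nodes[node_id]["labels"])

    def related(self, node_id: str, rel_type: str) -> list[str]:
        return self.rels.get((node_id, rel_type), [])


def _open_store(config: ImportConfig) -> SchemaStore:
    uri = config.db_uri
    if uri.startswith("file:"):
        uri = uri[len("file:"):]
    if not uri:
        raise ImportError_("no store given: set ImportConfig.db_uri or pass store=")
    return JsonSchemaStore.from_json(uri)


def _check_schema(store: SchemaStore) -> None:
    for label in _REQUIRED_LABELS:
        if not store.node_ids_with_label(label):
            raise ImportError_(f"schema mismatch: no nodes labelled {label!r}")
    version = getattr(store, "schema_version", None)
    if version is not None and version != PINNED_SCHEMA_VERSION:
        warnings.warn(
            f"store declares schema version {version}; this importer targets "
            f"version {PINNED_SCHEMA_VERSION} naming — proceeding best-effort",
            stacklevel=3,
        )


def _entity_record(store: SchemaStore, node_id: str) -> NodeRecord:
    props = store.node_properties(node_id)
    display = props.get("displayName", "")
    # referenceEntity carries identity metadata only; fall back to its name.
    if not display:
        for ref in store.related(node_id, "referenceEntity"):
            display = store.node_properties(ref).get("displayName", "")
            if display:
                break
    return NodeRecord(
        node_id=props.get("stId", node_id),
        node_class=PHYSICAL_ENTITY,
        display_name=display,
        compartments=_compartments(store, node_id),
        schema_category=props.get("schemaClass", "PhysicalEntity"),
    )


def _compartments(store: SchemaStore, node_id: str) -> frozenset[str]:
    accs = []
    for c in store.related(node_id, "compartment"):
        props = store.node_properties(c)
        acc = props.get("accession") or props.get("stId") or c
        if acc and not str(acc).startswith("GO:"):
            acc = f"GO:{acc}"
        accs.append(str(acc))
    return frozenset(accs)


def build_graph(config: ImportConfig, store: SchemaStore | None = None) -> ReactionGraph:
    """Extract the species' bipartite reaction multigraph from a store.

    Deterministic and idempotent: the same store and config always yield
    equal graphs.  Events retained by the species filter are kept even when
    no entity relationship survives — isolated events are real weakly
    connected components of the network, not noise.
    """
    if store is None:
        store = _open_store(config)
    _check_schema(store)
    pattern = config.pattern

    graph = ReactionGraph(species=config.species_code)
    entity_by_store_id: dict[str, str] = {}

    def ensure_entity(store_id: str) -> str:
        if store_id not in entity_by_store_id:
            record = _entity_record(store, store_id)
            if record.node_id not in graph:
                graph.add_node(record)
            entity_by_store_id[store_id] = record.node_id
        return entity_by_store_id[store_id]

    for ev in sorted(store.node_ids_with_label("ReactionLikeEvent")):
        props = store.node_properties(ev)
        st_id = props.get("stId", ev)
        species_codes = {
            store.node_properties(s).get("code")
            for s in store.related(ev, "species")
        }
        if config.species_code not in species_codes and not pattern.fullmatch(st_id):
            continue

        graph.add_node(
            NodeRecord(
                node_id=st_id,
                node_class=EVENT,
                display_name=props.get("displayName", ""),
                compartments=_compartments(store, ev),
                schema_category=props.get("schemaClass", "Reaction"),
                is_generic=pattern.fullmatch(st_id) is not None,
            )
        )

        for ent in store.related(ev, "input"):
            graph.add_edge(ensure_entity(ent), st_id, "input")
        for ent in store.related(ev, "output"):
            graph.add_edge(st_id, ensure_entity(ent), "output")
        for ca in store.related(ev, "catalystActivity"):
            for ent in store.related(ca, "physicalEntity"):
                graph.add_edge(ensure_entity(ent), st_id, "catalyst")
        for reg in store.related(ev, "regulatedBy"):
            reg_labels = store.labels(reg)
            if "PositiveRegulation" in reg_labels:
                sign = "positive_regulation"
            elif "NegativeRegulation" in reg_labels:
                sign = "negative_regulation"
            else:
                raise ImportError_(
                    f"regulation node {reg!r} carries neither PositiveRegulation "
                    "nor NegativeRegulation"
                )
            for ent in store.related(reg, "regulator"):
                graph.add_edge(ensure_entity(ent), st_id, sign)

    return graph


# ---------------------------------------------------------------------------
# Graph file round-trip: node-link JSON and GraphML.
# ---------------------------------------------------------------------------

def save_graph(graph: ReactionGraph, path: str | Path) -> None:
    """Serialize to ``.json`` (node-link) or ``.graphml`` by extension.

    Output is deterministic (sorted keys) so identical graphs serialize to
    byte-identical files.
    """
    path = Path(path)
    if path.suffix == ".json":
        with open(path, "w") as fh:
            json.dump(graph.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")
    elif path.suffix == ".graphml":
        g = nx.MultiDiGraph(species=graph.species)
        for r in sorted(graph.nodes(), key=lambda r: r.node_id):
            g.add_node(
                r.node_id,
                node_class=r.node_class,
                display_name=r.display_name,
                compartments=";".join(sorted(r.compartments)),
                schema_category=r.schema_category,
                is_generic=r.is_generic,
            )
        for e in graph.edges():
            g.add_edge(e.source, e.target, key=e.edge_key, edge_type=e.edge_type)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unsupported graph format {path.suffix!r}; use .json or .graphml")


def load_graph(path: str | Path) -> ReactionGraph:
    """Load a graph saved by :func:`save_graph`.

    ``save_graph`` then ``load_graph`` is the identity on (species, node
    records, typed-edge multiset); edge keys may be relabelled within a
    parallel bundle.
    """
    path = Path(path)
    if path.suffix == ".json":
        with open(path) as fh:
            try:
                data = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}: line {exc.lineno}: {exc.msg}") from exc
        return _from_node_link(data, str(path))
    if path.suffix == ".graphml":
        try:
            g = nx.read_graphml(path, force_multigraph=True)
        except Exception as exc:  # lxml/expat errors vary by backend
            raise ParseError(f"{path}: {exc}") from exc
        data = {
            "species": g.graph.get("species", ""),
            "nodes": [
                {
                    "node_id": n,
                    "node_class": d["node_class"],
                    "display_name": d.get("display_name", ""),
                    "compartments": [
                        c for c in d.get("compartments", "").split(";") if c
                    ],
                    "schema_category": d.get("schema_category", ""),
                    "is_generic": d.get("is_generic", None),
                }
                for n, d in g.nodes(data=True)
            ],
            "edges": [
                {"source": u, "target": v, "edge_type": d["edge_type"]}
                for u, v, d in g.edges(data=True)
            ],
        }
        return _from_node_link(data, str(path))
    raise ValueError(f"unsupported graph format {path.suffix!r}; use .json or .graphml")


def _from_node_link(data: dict, context: str) -> ReactionGraph:
    try:
        nodes = data["nodes"]
        edges = data["edges"]
    except (KeyError, TypeError) as exc:
        raise ParseError(f"{context}: missing top-level {exc} section") from None
    known = {n.get("node_id") for n in nodes}
    for i, e in enumerate(edges):
        for side in ("source", "target"):
            if e.get(side) not in known:
                raise ParseError(
                    f"{context}: edge #{i} references unknown node {e.get(side)!r}"
                )
    try:
        return ReactionGraph.from_dict(data)
    except (KeyError, TypeError) as exc:
        raise ParseError(f"{context}: malformed record: {exc}") from exc
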