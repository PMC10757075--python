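"""Cell-compartment hierarchy and per-compartment subgraph statistics.

Reaction-network nodes are annotated with cellular-component ontology terms
(compartments).  To study the network compartment by compartment, the
cellular-component containment hierarchy is pruned down to the compartments
that actually host reactions:

1. a dummy root is added with exactly two children — the *cell* term and
   the *extracellular region* term — so both sides of the plasma membrane
   hang off one handle;
2. every compartment annotating zero reaction (event) nodes is discarded —
   entities alone do not rescue a compartment;
3. each orphaned child is re-linked to the lowest non-discarded ancestor
   along *each* of its ancestral paths (deduplicated).  Containment in the
   ontology is a DAG, not a forest — a compartment can be part of several
   super-compartments — so the "lowest retained ancestor" can be plural and
   all of them are kept as parents, preserving the DAG shape.

The ontology is read from an OBO file via :mod:`obonet`; the relations
treated as containment are configurable and default to ``is_a`` together
with ``part_of``.

For each retained compartment the *induced subgraph* on the nodes labelled
with it (a node labelled with several compartments belongs to each of the
corresponding subgraphs) is summarized by its node, SCC and WCC counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import obonet
import pandas as pd

from .connectivity import strongly_connected_components, weakly_connected_components
from .model import EVENT, NodeRecord, ReactionGraph

__all__ = [
    "DUMMY_ROOT",
    "CELL",
    "EXTRACELLULAR",
    "HierarchyError",
    "CompartmentHierarchy",
    "CompartmentStats",
    "load_ontology",
    "build_hierarchy",
    "compartment_subgraph",
    "compartment_stats_table",
]

DUMMY_ROOT = "COMPARTMENT_ROOT"
CELL = "GO:0005623"
EXTRACELLULAR = "GO:0005576"

#: OBO relations treated as compartment containment by default.
DEFAULT_RELATIONS = ("is_a", "part_of")


class HierarchyError(Exception):
    """Ontology is unusable (e.g. the containment relation has a cycle)."""


@dataclass(frozen=True)
class CompartmentHierarchy:
    """Pruned compartment DAG rooted at a dummy node.

    ``parent_links`` holds (child, parent) pairs; ``retained`` is the set
    of compartments with at least one reaction node.  The two anchor terms
    (cell / extracellular region) are structural: they are always present
    as the dummy root's children, whether or not they host reactions.
    """

    compartments: frozenset[str]
    parent_links: frozenset[tuple[str, str]]
    retained: frozenset[str]
    names: dict[str, str]

    @property
    def root(self) -> str:
        return DUMMY_ROOT

    def parents(self, compartment: str) -> set[str]:
        return {p for c, p in self.parent_links if c == compartment}

    def children(self, compartment: str) -> set[str]:
        return {c for c, p in self.parent_links if p == compartment}

    def dag(self) -> nx.DiGraph:
        """Child -> parent digraph over all hierarchy compartments."""
        g = nx.DiGraph()
        g.add_nodes_from(self.compartments)
        g.add_edges_from(self.parent_links)
        return g

    def descendants(self, compartment: str) -> set[str]:
        """All compartments below (not including) the given one."""
        return set(nx.ancestors(self.dag(), compartment))


@dataclass(frozen=True)
class CompartmentStats:
    """Connectivity census of one compartment's induced subgraph."""

    compartment: str
    n_nodes: int
    n_scc: int
    n_wcc: int


def load_ontology(path: str | Path) -> nx.MultiDiGraph:
    """Read an OBO ontology into the child->parent multigraph convention."""
    return obonet.read_obo(str(path))


def _containment_dag(
    ontology: nx.MultiDiGraph, relations: tuple[str, ...]
) -> nx.DiGraph:
    dag = nx.DiGraph()
    dag.add_nodes_from(ontology.nodes)
    for child, parent, rel in ontology.edges(keys=True):
        if rel in relations:
            dag.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(dag):
        cycle = nx.find_cycle(dag)
        raise HierarchyError(f"containment relation has a cycle: {cycle}")
    return dag


def build_hierarchy(
    ontology: nx.MultiDiGraph | str | Path,
    graph: ReactionGraph,
    relations: tuple[str, ...] = DEFAULT_RELATIONS,
    cell: str = CELL,
    extracellular: str = EXTRACELLULAR,
) -> CompartmentHierarchy:
    """Prune the compartment ontology to the compartments hosting reactions.

    ``ontology`` is an OBO file path or an obonet-style multigraph (edges
    child -> parent keyed by relation).  Compartment accessions present in
    the graph but absent from the ontology are kept, with a warning, as
    leaves directly under the dummy root.
    """
    if isinstance(ontology, (str, Path)):
        ontology = load_ontology(ontology)
    dag = _containment_dag(ontology, relations)

    reaction_compartments: set[str] = set()
    for record in graph.nodes():
        if record.node_class == EVENT:
            reaction_compartments |= record.compartments

    anchors = {cell, extracellular}
    known_retained = reaction_compartments & set(dag.nodes)
    unknown = reaction_compartments - set(dag.nodes)
    # Anchors are structural even when the ontology lacks them entirely.
    keep = known_retained | anchors

    # Lowest retained ancestor(s) along every upward path, memoized.
    resolved: dict[str, frozenset[str]] = {}

    def lowest_kept_ancestors(term: str) -> frozenset[str]:
        if term in resolved:
            return resolved[term]
        out: set[str] = set()
        for parent in dag.successors(term):
            if parent in keep:
                out.add(parent)
            else:
                out |= lowest_kept_ancestors(parent)
        resolved[term] = frozenset(out)
        return resolved[term]

    links: set[tuple[str, str]] = {(cell, DUMMY_ROOT), (extracellular, DUMMY_ROOT)}
    names: dict[str, str] = {DUMMY_ROOT: "compartment root"}
    for term in (cell, extracellular):
        names[term] = ontology.nodes[term].get("name", term) if term in ontology else term

    for term in sorted(keep - anchors):
        parents = lowest_kept_ancestors(term)
        names[term] = ontology.nodes[term].get("name", term)
        if not parents:
            warnings.warn(
                f"compartment {term} has no retained ancestor in the ontology; "
                "keeping it as a leaf under the dummy root",
                stacklevel=2,
            )
            links.add((term, DUMMY_ROOT))
        else:
            links.update((term, p) for p in parents)

    for term in sorted(unknown):
        warnings.warn(
            f"compartment accession {term} annotates reactions but is not in "
            "the ontology; keeping it as a leaf under the dummy root",
            stacklevel=2,
        )
        names[term] = term
        links.add((term, DUMMY_ROOT))

    compartments = keep | unknown | {DUMMY_ROOT}
    return CompartmentHierarchy(
        compartments=frozenset(compartments),
        parent_links=frozenset(links),
        retained=frozenset(c for c in compartments if c in reaction_compartments),
        names=names,
    )


def compartment_subgraph(
    graph: ReactionGraph,
    compartment: str,
    hierarchy: CompartmentHierarchy | None = None,
    aggregate_descendants: bool = False,
) -> ReactionGraph:
    """Node-induced subgraph of one compartment.

    Membership uses direct labels; with ``aggregate_descendants=True`` the
    labels of every compartment below the given one in the hierarchy are
    unioned in as well (requires ``hierarchy``).  If a hierarchy is given,
    the compartment must be one of its members.
    """
    labels = {compartment}
    if hierarchy is not None:
        if compartment not in hierarchy.compartments:
            raise KeyError(f"compartment {compartment!r} is not in the hierarchy")
        if aggregate_descendants:
            labels |= hierarchy.descendants(compartment)
    elif aggregate_descendants:
        raise ValueError("aggregate_descendants requires a hierarchy")

    keep = [
        r.node_id for r in graph.nodes() if r.compartments & labels
    ]
    sub = ReactionGraph(species=graph.species)
    kept = set(keep)
    for node_id in keep:
        r = graph.node(node_id)
        sub.add_node(NodeRecord(
            node_id=r.node_id,
            node_class=r.node_class,
            display_name=r.display_name,
            compartments=r.compartments,
            schema_category=r.schema_category,
            is_generic=r.is_generic,
        ))
    for e in graph.edges():
        if e.source in kept and e.target in kept:
            sub.add_edge(e.source, e.target, e.edge_type)
    return sub


def compartment_stats_table(
    graph: ReactionGraph,
    hierarchy: CompartmentHierarchy,
    aggregate_descendants: bool = False,
) -> pd.DataFrame:
    """Per-compartment connectivity census over the retained compartments.

    Columns ``compartment``, ``name``, ``n_scc``, ``n_wcc``, ``n_nodes``;
    rows sorted by ``n_nodes`` descending (ties by accession).  Every row
    satisfies ``n_wcc <= n_scc <= n_nodes``.
    """
    rows = []
    for comp in sorted(hierarchy.retained):
        sub = compartment_subgraph(
            graph, comp, hierarchy, aggregate_descendants=aggregate_descendants
        )
        rows.append(
            {
                "compartment": comp,
                "name": hierarchy.names.get(comp, comp),
                "n_scc": len(strongly_connected_components(sub)),
                "n_wcc": len(weakly_connected_components(sub)),
                "n_nodes": sub.n_nodes,
            }
        )
    df = pd.DataFrame(
        rows, columns=["compartment", "name", "n_scc", "n_wcc", "n_nodes"]
    )
    if not df.empty:
        df = df.sort_values(
            ["n_nodes", "compartment"], ascending=[False, True], ignore_index=True
        )
    return df
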