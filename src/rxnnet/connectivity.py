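"""Connectivity structure: SCC/WCC decomposition and the condensation DAG.

Contracting every strongly connected component (SCC) of a digraph to a
single node yields its *condensation*, which is always acyclic.  For a
reaction network the condensation exposes the irreversible backbone of the
chemistry: sources are components nothing feeds into, and a giant SCC — if
one exists — is a large mutually-reachable core of entities and reactions.
SCCs are also the natural search space for attractors in qualitative
network dynamics, which is why the per-component compartment coverage is
reported alongside the sizes.

Decomposition is delegated to :mod:`networkx`; this module adds the
reaction-graph bookkeeping (compartment coverage, source census, the
summary record) and the diameter convention documented at
:func:`dag_diameter`.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .model import ReactionGraph

__all__ = [
    "CondensationResult",
    "ConnectivityReport",
    "strongly_connected_components",
    "weakly_connected_components",
    "condensation",
    "dag_diameter",
    "condensation_report",
]


@dataclass(frozen=True)
class CondensationResult:
    """The SCC partition of a graph together with its condensation DAG.

    ``components[i]`` is the node set of condensed node ``i``;
    ``dag_edges`` holds ordered component-index pairs (parallel crossings
    between two components collapse to a single DAG edge); ``sources`` are
    the condensed nodes with no incoming DAG edge.
    """

    components: tuple[frozenset[str], ...]
    dag_edges: frozenset[tuple[int, int]]
    membership: dict[str, int]
    sources: frozenset[int]

    @property
    def n_components(self) -> int:
        return len(self.components)

    def dag(self) -> nx.DiGraph:
        """The condensation as a simple digraph on component indices."""
        g = nx.DiGraph()
        g.add_nodes_from(range(len(self.components)))
        g.add_edges_from(self.dag_edges)
        return g

    def component_compartments(self, graph: ReactionGraph, index: int) -> set[str]:
        """Union of compartment labels over the component's member nodes."""
        out: set[str] = set()
        for node_id in self.components[index]:
            out |= graph.node(node_id).compartments
        return out


def strongly_connected_components(graph: ReactionGraph) -> list[set[str]]:
    """Maximal mutually-reachable node classes, singletons included."""
    return [set(c) for c in nx.strongly_connected_components(graph.nx_graph)]


def weakly_connected_components(graph: ReactionGraph) -> list[set[str]]:
    """Connectivity classes when edge direction is ignored."""
    return [set(c) for c in nx.weakly_connected_components(graph.nx_graph)]


def condensation(graph: ReactionGraph) -> CondensationResult:
    """Contract every SCC to one node; the result is a DAG."""
    g = graph.nx_graph
    sccs = list(nx.strongly_connected_components(g))
    cond = nx.condensation(g, scc=sccs)
    components = tuple(frozenset(c) for c in sccs)
    membership = dict(cond.graph["mapping"])
    dag_edges = frozenset(cond.edges())
    targets = {b for _, b in dag_edges}
    sources = frozenset(i for i in range(len(components)) if i not in targets)
    return CondensationResult(
        components=components,
        dag_edges=dag_edges,
        membership=membership,
        sources=sources,
    )


def dag_diameter(
    cond: CondensationResult | nx.DiGraph, undirected: bool = False
) -> int:
    """Longest finite shortest path in a DAG (0 for an edgeless one).

    A condensation is generally disconnected, so the all-pairs diameter is
    infinite under the textbook definition; the convention here takes the
    maximum over *reachable* ordered pairs, which is the only reading that
    yields one finite number.  With ``undirected=True`` direction is
    ignored and the maximum is taken within weak components instead.
    """
    dag = cond.dag() if isinstance(cond, CondensationResult) else cond
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("input is not acyclic; condense the graph first")
    search = dag.to_undirected(as_view=False) if undirected else dag
    best = 0
    for v in search.nodes:
        lengths = nx.single_source_shortest_path_length(search, v)
        if lengths:
            best = max(best, max(lengths.values()))
    return best


@dataclass(frozen=True)
class ConnectivityReport:
    """Global connectivity census of one reaction graph."""

    n_nodes: int
    n_edges: int
    n_condensed_nodes: int
    n_condensed_edges: int
    n_sources: int
    n_source_compartments: int
    n_compartments: int
    largest_scc_size: int
    largest_scc_fraction: float
    n_largest_scc_compartments: int
    singleton_fraction: float
    n_wcc: int
    largest_wcc_size: int
    diameter: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def condensation_report(graph: ReactionGraph) -> ConnectivityReport:
    """Summarize the condensation of a reaction graph.

    ``largest_wcc_size`` counts *condensed* nodes (weak components are
    identical before and after condensation, but their sizes are reported
    on the condensation, where the giant SCC is a single node).
    ``singleton_fraction`` is the fraction of original nodes that form a
    one-node SCC.  Compartment coverage of a set of components is the union
    of the compartment labels of their member nodes.
    """
    cond = condensation(graph)
    n = graph.n_nodes
    all_compartments: set[str] = set()
    for record in graph.nodes():
        all_compartments |= record.compartments

    source_compartments: set[str] = set()
    for i in cond.sources:
        source_compartments |= cond.component_compartments(graph, i)

    if cond.components:
        largest_idx = max(
            range(len(cond.components)), key=lambda i: len(cond.components[i])
        )
        largest = cond.components[largest_idx]
        largest_compartments = cond.component_compartments(graph, largest_idx)
    else:
        largest, largest_compartments = frozenset(), set()

    singletons = sum(1 for c in cond.components if len(c) == 1)
    dag = cond.dag()
    wccs = list(nx.weakly_connected_components(dag))

    return ConnectivityReport(
        n_nodes=n,
        n_edges=graph.n_edges,
        n_condensed_nodes=cond.n_components,
        n_condensed_edges=len(cond.dag_edges),
        n_sources=len(cond.sources),
        n_source_compartments=len(source_compartments),
        n_compartments=len(all_compartments),
        largest_scc_size=len(largest),
        largest_scc_fraction=len(largest) / n if n else 0.0,
        n_largest_scc_compartments=len(largest_compartments),
        singleton_fraction=singletons / n if n else 0.0,
        n_wcc=len(wccs),
        largest_wcc_size=max((len(c) for c in wccs), default=0),
        diameter=dag_diameter(cond),
    )
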