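"""Directed centrality measures for bipartite reaction multigraphs.

Five measures are provided, each in the direction variants that are
well-defined for it.  Throughout, :math:`d^+(v)` / :math:`d^-(v)` are
multigraph out-/in-degrees (parallel edges count) and :math:`N^+(v)` /
:math:`N^-(v)` are the *distinct* out-/in-neighbour sets; sums over a
neighbourhood therefore run over distinct nodes while the degrees inside
them count every edge.

* **degree centrality** ``DC±(v) = d±(v)`` — purely local.
* **H-index centrality** ``HC+(v)`` — the largest ``h`` such that at least
  ``h`` out-neighbours of ``v`` have out-degree at least ``h`` (the in
  variant uses in-neighbours and in-degrees).  Neighbour degrees are taken
  in the same direction as the measure; a switch is exposed for the
  alternative reading.
* **Laplacian centrality** ``LAPC+(v) = d+(v)² + d+(v) + 2 Σ_{u∈N+(v)} d+(u)``
  — the drop in the Laplacian energy of the graph when ``v`` is removed,
  sensitive to the 2-neighbourhood.
* **leverage centrality**
  ``LC+(v) = (1/d+(v)) Σ_{u∈N+(v)} (d+(v) − d+(u)) / (d+(v) + d+(u))``
  — in [−1, 1]; positive when ``v`` out-ranks its neighbours.  Defined as
  0 when ``d+(v) = 0`` (no neighbours carry no information).
* **closeness centrality** ``CC(v) = n / Σ_u d(u, v)`` with unweighted
  shortest directed distances *into* ``v``.  On a graph that is not
  strongly connected the literal formula degenerates (some distance is
  infinite), so the default ``mode="reachable"`` restricts both the
  numerator and the sum to the nodes that reach ``v``; ``mode="strict"``
  applies the literal formula, scoring 0 for any node not reachable from
  everywhere.  Both modes agree on strongly connected graphs.  Note values
  may exceed 1: the numerator is ``n``, not ``n − 1``.

For reaction networks the directions read naturally: the in-degree of an
event is its number of reactant/modifier slots, its out-degree the number
of products; the in-degree of an entity counts the reactions producing it,
its out-degree the reactions consuming or modulated by it.

Betweenness and coreness are deliberately not offered: their standard
definitions do not apply to multigraphs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import networkx as nx
import pandas as pd

from .model import ReactionGraph

__all__ = [
    "CentralityResult",
    "degree_centrality",
    "h_index_centrality",
    "laplacian_centrality",
    "leverage_centrality",
    "closeness_centrality",
    "category_degree_summary",
]

_DIRECTIONS = ("in", "out", "total")


@dataclass(frozen=True)
class CentralityResult:
    """Scores of one measure, one direction, for every node of a graph."""

    measure: str
    direction: str
    scores: dict[str, float]

    def to_series(self) -> pd.Series:
        s = pd.Series(self.scores, name=f"{self.measure}_{self.direction}")
        s.index.name = "node_id"
        return s

    def top(self, k: int = 10) -> list[tuple[str, float]]:
        """The k highest-scoring nodes (ties broken by node id)."""
        return sorted(self.scores.items(), key=lambda kv: (-kv[1], kv[0]))[:k]


def _check_direction(direction: str, allowed: tuple[str, ...]) -> None:
    if direction not in allowed:
        raise ValueError(f"direction must be one of {allowed}, got {direction!r}")


def _as_nx(graph: "ReactionGraph | nx.MultiDiGraph | nx.DiGraph") -> nx.DiGraph:
    """The measures are generic digraph measures; accept bare nx graphs too."""
    g = graph.nx_graph if isinstance(graph, ReactionGraph) else graph
    if not g.is_directed():
        raise TypeError("centrality measures here are defined on directed graphs")
    return g


def _degree_fn(
    g: nx.DiGraph, direction: str, edge_types: Iterable[str] | None
) -> Callable[[str], int]:
    if edge_types is None:
        if direction == "in":
            return lambda v: g.in_degree(v)
        if direction == "out":
            return lambda v: g.out_degree(v)
        return lambda v: g.in_degree(v) + g.out_degree(v)
    allowed = frozenset(edge_types)

    def d_in(v):
        return sum(1 for *_, t in g.in_edges(v, data="edge_type") if t in allowed)

    def d_out(v):
        return sum(1 for *_, t in g.out_edges(v, data="edge_type") if t in allowed)

    if direction == "in":
        return d_in
    if direction == "out":
        return d_out
    return lambda v: d_in(v) + d_out(v)


def _neighbor_fn(
    g: nx.DiGraph, direction: str, edge_types: Iterable[str] | None
) -> Callable[[str], set[str]]:
    if edge_types is None:
        if direction == "in":
            return lambda v: set(g.predecessors(v))
        return lambda v: set(g.successors(v))
    allowed = frozenset(edge_types)
    if direction == "in":
        return lambda v: {
            u for u, _, t in g.in_edges(v, data="edge_type") if t in allowed
        }
    return lambda v: {
        w for _, w, t in g.out_edges(v, data="edge_type") if t in allowed
    }


def degree_centrality(
    graph: ReactionGraph,
    direction: str = "total",
    edge_types: Iterable[str] | None = None,
) -> CentralityResult:
    """DC±: the multigraph in-, out- or total degree of every node."""
    _check_direction(direction, _DIRECTIONS)
    g = _as_nx(graph)
    deg = _degree_fn(g, direction, edge_types)
    return CentralityResult(
        "DC", direction, {v: float(deg(v)) for v in g.nodes}
    )


def h_index(degrees: Iterable[int]) -> int:
    """The classical h-index of a multiset of non-negative integers."""
    ds = sorted(degrees, reverse=True)
    h = 0
    for i, d in enumerate(ds, start=1):
        if d >= i:
            h = i
        else:
            break
    return h


def h_index_centrality(
    graph: ReactionGraph,
    direction: str,
    edge_types: Iterable[str] | None = None,
    neighbor_degree_direction: str | None = None,
) -> CentralityResult:
    """HC±: h-index of a node's neighbourhood degrees.

    ``neighbor_degree_direction`` defaults to ``direction`` (out-measure
    looks at out-degrees of out-neighbours); pass a different direction to
    change the reading.
    """
    _check_direction(direction, ("in", "out"))
    nbr_dir = neighbor_degree_direction or direction
    _check_direction(nbr_dir, _DIRECTIONS)
    g = _as_nx(graph)
    nbrs = _neighbor_fn(g, direction, edge_types)
    deg = _degree_fn(g, nbr_dir, edge_types)
    return CentralityResult(
        "HC",
        direction,
        {v: float(h_index(deg(u) for u in nbrs(v))) for v in g.nodes},
    )


def laplacian_centrality(
    graph: ReactionGraph,
    direction: str,
    edge_types: Iterable[str] | None = None,
) -> CentralityResult:
    """LAPC±(v) = d±(v)² + d±(v) + 2 Σ_{u ∈ N±(v)} d±(u)."""
    _check_direction(direction, ("in", "out"))
    g = _as_nx(graph)
    nbrs = _neighbor_fn(g, direction, edge_types)
    deg = _degree_fn(g, direction, edge_types)
    scores = {}
    for v in g.nodes:
        d = deg(v)
        scores[v] = float(d * d + d + 2 * sum(deg(u) for u in nbrs(v)))
    return CentralityResult("LAPC", direction, scores)


def leverage_centrality(
    graph: ReactionGraph,
    direction: str,
    edge_types: Iterable[str] | None = None,
) -> CentralityResult:
    """LC±(v) = (1/d±(v)) Σ_{u ∈ N±(v)} (d±(v) − d±(u)) / (d±(v) + d±(u)).

    Degree-zero nodes score 0.  A neighbour of degree 0 contributes a term
    of exactly 1 (the denominator is then d±(v) > 0).
    """
    _check_direction(direction, ("in", "out"))
    g = _as_nx(graph)
    nbrs = _neighbor_fn(g, direction, edge_types)
    deg = _degree_fn(g, direction, edge_types)
    scores = {}
    for v in g.nodes:
        d = deg(v)
        if d == 0:
            scores[v] = 0.0
            continue
        scores[v] = sum((d - deg(u)) / (d + deg(u)) for u in nbrs(v)) / d
    return CentralityResult("LC", direction, scores)


def closeness_centrality(
    graph: ReactionGraph,
    mode: str = "reachable",
    direction: str = "in",
) -> CentralityResult:
    """CC(v) = n / Σ_u d(u, v), distances directed into v.

    ``mode="reachable"`` (default): n and the sum range over the set of
    nodes with a finite distance to v (which always contains v itself);
    nodes nothing else reaches score 0.  ``mode="strict"``: n = |V| and any
    unreachable node makes the score 0.  ``direction="out"`` measures
    distances *from* v instead — a convenience variant, not part of the
    canonical definition.

    Parallel edges are irrelevant to shortest paths, so distances are
    computed on the simple projection of the multigraph.
    """
    if mode not in ("reachable", "strict"):
        raise ValueError(f"mode must be 'reachable' or 'strict', got {mode!r}")
    _check_direction(direction, ("in", "out"))
    simple = nx.DiGraph(_as_nx(graph))
    # BFS from v on the reversed graph enumerates exactly the nodes with a
    # finite directed distance INTO v.
    search = simple.reverse(copy=False) if direction == "in" else simple
    n = simple.number_of_nodes()
    scores = {}
    for v in simple.nodes:
        lengths = nx.single_source_shortest_path_length(search, v)
        total = sum(lengths.values())
        if mode == "strict":
            scores[v] = float(n) / total if len(lengths) == n and total > 0 else 0.0
        else:
            scores[v] = len(lengths) / total if total > 0 else 0.0
    return CentralityResult("CC", direction, scores)


def category_degree_summary(graph: ReactionGraph) -> pd.DataFrame:
    """Mean in- and out-degree per schema category.

    One row per category present in the graph, columns
    ``schema_category``, ``mean_in_degree``, ``mean_out_degree``,
    ``n_nodes``; sorted by category.
    """
    rows = [
        {
            "schema_category": r.schema_category,
            "in_degree": graph.in_degree(r.node_id),
            "out_degree": graph.out_degree(r.node_id),
        }
        for r in graph.nodes()
    ]
    if not rows:
        return pd.DataFrame(
            columns=["schema_category", "mean_in_degree", "mean_out_degree", "n_nodes"]
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby("schema_category")
        .agg(
            mean_in_degree=("in_degree", "mean"),
            mean_out_degree=("out_degree", "mean"),
            n_nodes=("in_degree", "size"),
        )
        .reset_index()
        .sort_values("schema_category", ignore_index=True)
    )
    return out


#: Registry used by the command-line layer.
MEASURES: Mapping[str, Callable] = {
    "dc": degree_centrality,
    "hc": h_index_centrality,
    "lapc": laplacian_centrality,
    "lc": leverage_centrality,
}
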