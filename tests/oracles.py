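"""Naive reference implementations used as oracles in the tests.

Everything here works from a plain node list and a plain edge list
(``(source, target)`` pairs with multiplicity) and literally enumerates the
definitions — h values one by one, all-pairs BFS, boolean transitive
closure, union-find — independently of the implementations under test.
"""

from __future__ import annotations

from collections import deque


def out_degree(edges, v):
    return sum(1 for s, _ in edges if s == v)


def in_degree(edges, v):
    return sum(1 for _, t in edges if t == v)


def out_neighbors(edges, v):
    return {t for s, t in edges if s == v}


def in_neighbors(edges, v):
    return {s for s, t in edges if t == v}


def _dir(edges, direction):
    deg = in_degree if direction == "in" else out_degree
    nbr = in_neighbors if direction == "in" else out_neighbors
    return deg, nbr


def degree_scores(nodes, edges, direction):
    if direction == "total":
        return {v: in_degree(edges, v) + out_degree(edges, v) for v in nodes}
    deg, _ = _dir(edges, direction)
    return {v: deg(edges, v) for v in nodes}


def h_index_scores(nodes, edges, direction):
    """max h such that at least h neighbours have degree >= h, by enumeration."""
    deg, nbr = _dir(edges, direction)
    scores = {}
    for v in nodes:
        nd = [deg(edges, u) for u in nbr(edges, v)]
        best = 0
        for h in range(len(nd) + 1):
            if sum(1 for d in nd if d >= h) >= h:
                best = h
        scores[v] = best
    return scores


def laplacian_scores(nodes, edges, direction):
    deg, nbr = _dir(edges, direction)
    out = {}
    for v in nodes:
        d = deg(edges, v)
        out[v] = d * d + d + 2 * sum(deg(edges, u) for u in nbr(edges, v))
    return out


def leverage_scores(nodes, edges, direction):
    deg, nbr = _dir(edges, direction)
    out = {}
    for v in nodes:
        d = deg(edges, v)
        if d == 0:
            out[v] = 0.0
        else:
            out[v] = sum(
                (d - deg(edges, u)) / (d + deg(edges, u)) for u in nbr(edges, v)
            ) / d
    return out


def bfs_distances(nodes, edges, source):
    adj = {v: set() for v in nodes}
    for s, t in edges:
        adj[s].add(t)
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                queue.append(w)
    return dist


def closeness_scores(nodes, edges, mode="reachable"):
    """CC(v) from a full all-pairs BFS table, distances into v."""
    nodes = list(nodes)
    dist_from = {u: bfs_distances(nodes, edges, u) for u in nodes}
    n = len(nodes)
    scores = {}
    for v in nodes:
        into = [dist_from[u][v] for u in nodes if v in dist_from[u]]
        total = sum(into)
        if mode == "strict":
            scores[v] = n / total if len(into) == n and total > 0 else 0.0
        else:
            scores[v] = len(into) / total if total > 0 else 0.0
    return scores


def sccs(nodes, edges):
    """SCC partition from the boolean transitive closure (O(n^3))."""
    nodes = list(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    reach = [[False] * n for _ in range(n)]
    for i in range(n):
        reach[i][i] = True
    for s, t in edges:
        reach[idx[s]][idx[t]] = True
    for k in range(n):
        rk = reach[k]
        for i in range(n):
            if reach[i][k]:
                ri = reach[i]
                for j in range(n):
                    if rk[j]:
                        ri[j] = True
    comps = []
    assigned = set()
    for i, v in enumerate(nodes):
        if v in assigned:
            continue
        comp = {
            nodes[j]
            for j in range(n)
            if reach[i][j] and reach[j][i]
        }
        assigned |= comp
        comps.append(comp)
    return comps


def wccs(nodes, edges):
    """Weak components by union-find."""
    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for s, t in edges:
        rs, rt = find(s), find(t)
        if rs != rt:
            parent[rs] = rt
    groups = {}
    for v in nodes:
        groups.setdefault(find(v), set()).add(v)
    return list(groups.values())


def diameter(nodes, edges):
    """Longest finite shortest path via all-pairs BFS."""
    best = 0
    for u in nodes:
        dist = bfs_distances(nodes, edges, u)
        if dist:
            best = max(best, max(dist.values()))
    return best
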