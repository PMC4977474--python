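"""Brute-force reference implementations used only as test oracles.

Everything here is written from first principles (pair scans, BFS,
power-set enumeration) and deliberately never calls the library code or the
graph routines it delegates to.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations


def edge_set(graph) -> set[tuple[str, str]]:
    """Canonical undirected edge set by scanning all vertex pairs."""
    nodes = list(graph.nodes)
    out = set()
    for u, v in combinations(nodes, 2):
        if graph.has_edge(u, v):
            out.add((u, v) if u <= v else (v, u))
    return out


def local_cc(graph, v) -> float:
    nbrs = list(graph.neighbors(v))
    d = len(nbrs)
    if d < 2:
        return 0.0
    links = sum(1 for a, b in combinations(nbrs, 2) if graph.has_edge(a, b))
    return 2.0 * links / (d * (d - 1))


def mean_cc(graph) -> float:
    nodes = list(graph.nodes)
    return sum(local_cc(graph, v) for v in nodes) / len(nodes)


def bfs_distances(graph, source) -> dict:
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for w in graph.neighbors(u):
            if w not in dist:
                dist[w] = dist[u] + 1
                q.append(w)
    return dist


def mean_path(graph) -> float:
    """Average shortest-path length over reachable unordered pairs."""
    nodes = list(graph.nodes)
    total, n_pairs = 0, 0
    for i, u in enumerate(nodes):
        dist = bfs_distances(graph, u)
        for v in nodes[i + 1 :]:
            if v in dist:
                total += dist[v]
                n_pairs += 1
    return total / n_pairs


def components(graph) -> list[set]:
    seen: set = set()
    comps = []
    for v in graph.nodes:
        if v in seen:
            continue
        comp = set(bfs_distances(graph, v))
        seen |= comp
        comps.append(comp)
    return comps


def degree_tally(graph) -> dict[int, int]:
    tally: dict[int, int] = {}
    for v in graph.nodes:
        d = sum(1 for _ in graph.neighbors(v))
        tally[d] = tally.get(d, 0) + 1
    return tally


def is_clique(graph, members) -> bool:
    return all(graph.has_edge(a, b) for a, b in combinations(members, 2))


def maximal_cliques_powerset(graph) -> set[frozenset]:
    """All maximal cliques of size >= 2 by power-set enumeration (|V| <= ~12)."""
    nodes = list(graph.nodes)
    cliques = [
        frozenset(c)
        for size in range(2, len(nodes) + 1)
        for c in combinations(nodes, size)
        if is_clique(graph, c)
    ]
    return {
        c for c in cliques
        if not any(c < other for other in cliques)
    }


def induced_density(graph, members) -> float:
    members = list(members)
    j = len(members)
    e = sum(1 for a, b in combinations(members, 2) if graph.has_edge(a, b))
    return e / (j * (j - 1) / 2)
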