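"""Independent brute-force reference implementations used only by tests.

Everything here is written from the definitions, by enumeration — no
networkx, no scipy graph routines — so it can serve as an oracle for the
library's implementations on small graphs.
"""

from __future__ import annotations

import itertools
import math

Adj = dict[str, set[str]]


def adjacency(nodes: list[str], edges: list[tuple[str, str]]) -> Adj:
    adj: Adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def brute_components(adj: Adj) -> list[set[str]]:
    unseen = set(adj)
    comps = []
    while unseen:
        start = unseen.pop()
        comp = {start}
        frontier = [start]
        while frontier:
            node = frontier.pop()
            for nb in adj[node]:
                if nb in unseen:
                    unseen.discard(nb)
                    comp.add(nb)
                    frontier.append(nb)
        comps.append(comp)
    return comps


def brute_articulation_points(adj: Adj) -> set[str]:
    """Delete each node in turn and recount components."""
    base = len(brute_components(adj))
    out = set()
    for node in adj:
        reduced = {n: nbrs - {node} for n, nbrs in adj.items() if n != node}
        if len(brute_components(reduced)) > base - (1 if len(adj[node]) == 0 else 0):
            out.add(node)
    return out


def _shortest_path_counts(adj: Adj, source: str) -> tuple[dict[str, int], dict[str, int]]:
    """BFS distances and shortest-path counts from one source."""
    dist = {source: 0}
    sigma = {source: 1}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    sigma[v] = 0
                    nxt.append(v)
                if dist[v] == dist[u] + 1:
                    sigma[v] += sigma[u]
        frontier = nxt
    return dist, sigma


def brute_betweenness(adj: Adj) -> dict[str, float]:
    """Pair-by-pair shortest-path counting, normalized by (n−1)(n−2)/2."""
    nodes = sorted(adj)
    n = len(nodes)
    bc = {v: 0.0 for v in nodes}
    if n < 3:
        return bc
    dist = {}
    sigma = {}
    for s in nodes:
        dist[s], sigma[s] = _shortest_path_counts(adj, s)
    for s, t in itertools.combinations(nodes, 2):
        if t not in dist[s]:
            continue
        d_st = dist[s][t]
        total = sigma[s][t]
        for v in nodes:
            if v in (s, t) or v not in dist[s] or v not in dist[t]:
                continue
            if dist[s][v] + dist[t][v] == d_st:
                bc[v] += sigma[s][v] * sigma[t][v] / total
    norm = (n - 1) * (n - 2) / 2
    return {v: bc[v] / norm for v in nodes}


def brute_clustering(adj: Adj) -> dict[str, float]:
    out = {}
    for node, nbrs in adj.items():
        k = len(nbrs)
        if k < 2:
            out[node] = 0.0
            continue
        links = sum(1 for a, b in itertools.combinations(sorted(nbrs), 2) if b in adj[a])
        out[node] = links / (k * (k - 1) / 2)
    return out


def brute_optimal_paths(d: list[list[float]], tol: float = 1e-9):
    """Exhaustive simple-path search on the complete graph.

    Returns (best_length, interior_nodes) per ordered index pair: the
    minimum total step distance over all simple paths, and the set of
    intermediate nodes lying on at least one path within ``tol`` of the
    optimum.  Factorial cost: keep n ≤ 8.
    """
    n = len(d)
    best = [[0.0 if i == j else math.inf for j in range(n)] for i in range(n)]
    interior: list[list[set[int]]] = [[set() for _ in range(n)] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            others = [k for k in range(n) if k not in (i, j)]
            paths = []
            for r in range(len(others) + 1):
                for mid in itertools.permutations(others, r):
                    seq = (i, *mid, j)
                    length = sum(d[a][b] for a, b in zip(seq, seq[1:]))
                    paths.append((length, set(mid)))
            opt = min(length for length, _ in paths)
            on_opt: set[int] = set()
            for length, mid in paths:
                if length <= opt + tol + tol * abs(opt):
                    on_opt |= mid
            best[i][j] = best[j][i] = opt
            interior[i][j] = interior[j][i] = on_opt
    return best, interior


def brute_max_product(d: list[list[float]], decay: float, tol: float = 1e-9):
    """Max product of exp(−decay·step) over all simple paths, per pair."""
    best, _ = brute_optimal_paths(d, tol)
    n = len(d)
    return [
        [1.0 if i == j else math.exp(-decay * best[i][j]) for j in range(n)] for i in range(n)
    ]


def brute_gbc(areas: list[float], d: list[list[float]], decay: float, tol: float = 1e-9):
    """GBC by exhaustive optimal-path enumeration (pairs i<j, any tie)."""
    best, interior = brute_optimal_paths(d, tol)
    n = len(d)
    gbc = [0.0] * n
    for i in range(n):
        for j in range(i + 1, n):
            weight = areas[i] * areas[j] * math.exp(-decay * best[i][j])
            for k in interior[i][j]:
                gbc[k] += weight
    return gbc
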