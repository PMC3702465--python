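"""Independent brute-force oracles used to validate the implementation.

Everything here is written from first principles (plain BFS / enumeration /
dense linear algebra) and deliberately avoids the code paths under test.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def bfs_distances(adj: dict, source) -> dict:
    """Plain BFS shortest-path distances from ``source``."""
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def enumerate_shortest_paths(adj: dict, s, t) -> list[tuple]:
    """Every shortest s-t path, by breadth-limited DFS over BFS levels."""
    if s == t:
        return [(s,)]
    dist = bfs_distances(adj, s)
    if t not in dist:
        return []
    dist_t = bfs_distances(adj, t)
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(tuple(path))
            return
        # expand along neighbours one BFS level deeper that still reach t on
        # a geodesic
        for v in adj[u]:
            if dist.get(v) == dist[u] + 1 and v in dist_t and dist[v] + dist_t[v] == dist[t]:
                extend(path + [v])

    extend([s])
    return paths


def brute_force_betweenness(adj: dict) -> dict:
    """Unnormalized betweenness over unordered pairs, endpoints excluded,
    by literal enumeration of all shortest paths."""
    nodes = sorted(adj)
    cb = {v: 0.0 for v in nodes}
    for j, k in itertools.combinations(nodes, 2):
        paths = enumerate_shortest_paths(adj, j, k)
        if not paths:
            continue
        sigma = len(paths)
        for v in nodes:
            if v in (j, k):
                continue
            through = sum(1 for p in paths if v in p)
            cb[v] += through / sigma
    return cb


def rwr_linear_solve(adj_matrix: np.ndarray, p0: np.ndarray, r: float) -> np.ndarray:
    """Closed-form fixed point p = r (I - (1-r) W)^-1 p0 with column-normalized W."""
    colsum = adj_matrix.sum(axis=0)
    w = np.divide(adj_matrix, colsum, out=np.zeros_like(adj_matrix, dtype=float), where=colsum > 0)
    n = len(p0)
    return r * np.linalg.solve(np.eye(n) - (1 - r) * w, p0)


def graph_to_adj(g) -> dict:
    """networkx graph -> plain adjacency dict of sets."""
    return {v: set(g.neighbors(v)) for v in g.nodes}
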