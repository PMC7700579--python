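"""Independent brute-force oracles for network statistics.

These deliberately avoid networkx and the package's vectorized code:
distances come from a hand-rolled BFS and geodesic counts from explicit
path enumeration, so they can cross-check the real implementations.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def bfs_distances(adj: np.ndarray, source: int) -> dict[int, int]:
    n = adj.shape[0]
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in range(n):
            if adj[u, v] and v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def enumerate_geodesics(adj: np.ndarray, j: int, k: int) -> list[tuple[int, ...]]:
    """All shortest directed paths from j to k, by bounded DFS."""
    dist = bfs_distances(adj, j)
    if k not in dist:
        return []
    target = dist[k]
    out: list[tuple[int, ...]] = []
    stack = [(j, (j,))]
    while stack:
        node, path = stack.pop()
        if node == k and len(path) - 1 == target:
            out.append(path)
            continue
        if len(path) - 1 >= target:
            continue
        for v in range(adj.shape[0]):
            if adj[node, v] and v not in path:
                stack.append((v, path + (v,)))
    return out


def brute_betweenness(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(raw, normalized) betweenness by exhaustive geodesic enumeration."""
    n = adj.shape[0]
    ordered = np.zeros(n)
    for j in range(n):
        for k in range(n):
            if j == k:
                continue
            paths = enumerate_geodesics(adj, j, k)
            if not paths:
                continue
            for q in range(n):
                if q in (j, k):
                    continue
                through = sum(1 for p in paths if q in p[1:-1])
                ordered[q] += through / len(paths)
    raw = ordered / 2.0
    norm = ordered / ((n - 1) * (n - 2)) if n >= 3 else np.zeros(n)
    return raw, norm


def brute_closeness(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(raw, normalized) closeness on the symmetrized graph, unreachable = n."""
    n = adj.shape[0]
    sym = ((adj + adj.T) > 0).astype(int)
    raw = np.zeros(n)
    norm = np.zeros(n)
    for q in range(n):
        dist = bfs_distances(sym, q)
        total = sum(dist.get(j, n) for j in range(n) if j != q)
        raw[q] = 1.0 / total
        norm[q] = (n - 1) / total
    return raw, norm


def brute_counts(adj: np.ndarray) -> tuple[int, int, int, int]:
    """(connected_pairs, directed_ties, alpha, beta) by explicit loops."""
    n = adj.shape[0]
    directed = 0
    alpha = 0
    beta = 0
    for i in range(n):
        for j in range(n):
            if i != j and adj[i, j]:
                directed += 1
    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j] and adj[j, i]:
                alpha += 1
            elif adj[i, j] or adj[j, i]:
                beta += 1
    return alpha + beta, directed, alpha, beta


def brute_density(adj: np.ndarray) -> float:
    pairs, _, _, _ = brute_counts(adj)
    t = adj.shape[0]
    return pairs / (t * (t - 1) / 2)


def brute_level(adj: np.ndarray) -> float | None:
    _, _, alpha, beta = brute_counts(adj)
    if alpha + beta == 0:
        return None
    return 1.0 - alpha / (alpha + beta)


def brute_efficiency(adj: np.ndarray) -> float:
    pairs, _, _, _ = brute_counts(adj)
    t = adj.shape[0]
    return 1.0 - (pairs - (t - 1)) / (t * (t - 1) / 2 - (t - 1))


def random_digraph(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    adj = (rng.random((n, n)) < p).astype(int)
    np.fill_diagonal(adj, 0)
    return adj
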