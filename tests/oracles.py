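"""Independent reference implementations used only to check the package.

These are deliberately naive — direct transcriptions of definitions — and
share no code path with the implementation under test.
"""

from __future__ import annotations

import math
from collections import deque
from fractions import Fraction

import numpy as np


def naive_tom(a: np.ndarray) -> np.ndarray:
    """Triple-loop topological overlap: (l_ij + a_ij)/(min(k_i,k_j)+1-a_ij)."""
    n = a.shape[0]
    k = [sum(a[i][j] for j in range(n)) for i in range(n)]
    tom = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                tom[i][j] = 1.0
                continue
            l_ij = sum(a[i][u] * a[u][j] for u in range(n))
            tom[i][j] = (l_ij + a[i][j]) / (min(k[i], k[j]) + 1.0 - a[i][j])
    return tom


def brute_force_betweenness(nodes: list, edges: list[tuple]) -> dict:
    """Betweenness by explicit enumeration of all shortest paths.

    For every ordered pair (s, t) the shortest paths are enumerated through a
    BFS predecessor DAG; each interior vertex of each path receives
    1/(number of shortest s-t paths).  Undirected pairs are counted once.
    """
    adj: dict = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)

    def bfs(s):
        dist = {s: 0}
        preds: dict = {v: [] for v in nodes}
        q = deque([s])
        while q:
            u = q.popleft()
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    q.append(w)
                if dist.get(w) == dist[u] + 1:
                    preds[w].append(u)
        return dist, preds

    btw = {v: 0.0 for v in nodes}
    node_list = list(nodes)
    for si in range(len(node_list)):
        s = node_list[si]
        dist, preds = bfs(s)
        for t in node_list[si + 1:]:
            if t not in dist or t == s:
                continue

            paths: list[list] = []

            def walk(v, acc):
                if v == s:
                    paths.append(acc + [s])
                    return
                for p in preds[v]:
                    walk(p, acc + [v])

            walk(t, [])
            share = 1.0 / len(paths)
            for path in paths:
                for interior in path[1:-1]:
                    btw[interior] += share
    return btw


def exact_hypergeom_upper(N: int, M: int, n: int, m: int) -> Fraction:
    """P(X >= m) with exact rational arithmetic."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for i in range(max(m, 0), min(M, n) + 1):
        if n - i > N - M:
            continue
        acc += Fraction(math.comb(M, i) * math.comb(N - M, n - i), total)
    return acc


def two_pass_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook two-pass covariance / std-product Pearson estimate."""
    mx, my = x.mean(), y.mean()
    cov = ((x - mx) * (y - my)).sum()
    sx = math.sqrt(((x - mx) ** 2).sum())
    sy = math.sqrt(((y - my) ** 2).sum())
    return cov / (sx * sy)


def prim_mst_weight(n: int, weight: np.ndarray) -> float:
    """Total weight of an MST over the complete graph, by Prim's algorithm."""
    in_tree = [False] * n
    best = [math.inf] * n
    best[0] = 0.0
    total = 0.0
    for _ in range(n):
        u = min((i for i in range(n) if not in_tree[i]), key=lambda i: best[i])
        in_tree[u] = True
        total += best[u]
        for v in range(n):
            if not in_tree[v] and weight[u][v] < best[v]:
                best[v] = weight[u][v]
    return total
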