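"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and, where feasible, the
libraries) they are checking: exact rational combinatorics for the
hypergeometric tail, a triple loop for topological overlap, exhaustive
path enumeration for betweenness, and a literal step-up for BH.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import permutations
from math import comb

import numpy as np


def hypergeom_tail_exact(N: int, K: int, n: int, k: int) -> Fraction:
    """P(X >= k) as an exact rational: sum_j C(K,j) C(N-K,n-j) / C(N,n)."""
    total = comb(N, n)
    acc = 0
    for j in range(k, min(K, n) + 1):
        if n - j <= N - K:
            acc += comb(K, j) * comb(N - K, n - j)
    return Fraction(acc, total)


def tom_brute(a: np.ndarray) -> np.ndarray:
    """Topological overlap by explicit triple loop."""
    m = a.shape[0]
    k = a.sum(axis=1)
    out = np.zeros_like(a, dtype=float)
    for i in range(m):
        for j in range(m):
            if i == j:
                out[i, j] = 1.0
                continue
            shared = 0.0
            for u in range(m):
                shared += a[i, u] * a[u, j]
            out[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return out


def _all_shortest_paths(adj: dict[int, set[int]], s: int, t: int
                        ) -> list[tuple[int, ...]]:
    """Every shortest simple path between s and t by exhaustive enumeration
    (tiny graphs only)."""
    nodes = [v for v in adj if v not in (s, t)]
    paths = []
    for r in range(len(nodes) + 1):
        for mid in permutations(nodes, r):
            path = (s, *mid, t)
            if all(path[i + 1] in adj[path[i]] for i in range(len(path) - 1)):
                paths.append(path)
        if paths:
            break       # shortest length reached
    return paths


def betweenness_brute(edges: list[tuple[int, int]], nodes: list[int]
                      ) -> dict[int, float]:
    """Normalized betweenness centrality by enumerating all shortest paths."""
    adj: dict[int, set[int]] = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    raw = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            paths = _all_shortest_paths(adj, s, t)
            if not paths:
                continue
            for v in nodes:
                if v in (s, t):
                    continue
                through = sum(v in p for p in paths)
                raw[v] += through / len(paths)
    n = len(nodes)
    scale = 2.0 / ((n - 1) * (n - 2)) if n > 2 else 1.0
    return {v: raw[v] * scale for v in nodes}


def bh_step_up(pvalues: list[float]) -> list[float]:
    """Literal Benjamini-Hochberg step-up, input order restored."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q_sorted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        q_sorted[rank - 1] = running
    out = [0.0] * m
    for rank, i in enumerate(order):
        out[i] = q_sorted[rank]
    return out
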