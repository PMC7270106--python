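"""Independent brute-force oracles used to verify the implementation.

These deliberately avoid the package's own algorithms: the edit-distance
oracle enumerates every edit script recursively instead of running a DP,
and the transport oracle enumerates every vertex of the transportation
polytope (spanning trees of the complete bipartite supply/demand graph)
instead of solving a linear program.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations

import numpy as np


def brute_force_edit_distance(ref: tuple, hyp: tuple) -> int:
    """Minimum S+D+I over all edit scripts, by exhaustive recursion."""

    def go(i: int, j: int) -> int:
        if i == len(ref):
            return len(hyp) - j  # insert the rest
        if j == len(hyp):
            return len(ref) - i  # delete the rest
        best = go(i + 1, j + 1) + (ref[i] != hyp[j])  # match / substitute
        best = min(best, go(i + 1, j) + 1)  # delete ref[i]
        best = min(best, go(i, j + 1) + 1)  # insert hyp[j]
        return best

    return go(0, 0)


@lru_cache(maxsize=None)
def _spanning_trees(m: int, n: int) -> tuple[tuple[tuple[int, int], ...], ...]:
    """All spanning trees of K_{m,n}; nodes are rows 0..m-1 and columns
    m..m+n-1, edges are (row, col) cells of the transport plan."""
    nodes = m + n
    edges = [(i, m + j) for i in range(m) for j in range(n)]
    trees = []
    for subset in combinations(range(len(edges)), nodes - 1):
        parent = list(range(nodes))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ok = True
        for e in subset:
            a, b = edges[e]
            ra, rb = find(a), find(b)
            if ra == rb:
                ok = False
                break
            parent[ra] = rb
        if ok:
            trees.append(tuple(edges[e] for e in subset))
    return tuple(trees)


def brute_force_emd(a, b, cost) -> float:
    """Exact optimal transport cost between histograms ``a`` (rows) and
    ``b`` (columns) under ``cost`` by enumerating every basic feasible
    solution: each spanning tree of the bipartite graph determines a
    unique flow; the optimum is the cheapest tree with nonnegative flow.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    cost = np.asarray(cost, dtype=float)
    m, n = len(a), len(b)
    best = np.inf
    for tree in _spanning_trees(m, n):
        # strip leaves: a leaf's single edge must carry exactly the
        # leaf's remaining mass (rows supply, columns demand alike)
        rem = {i: a[i] for i in range(m)}
        rem.update({m + j: b[j] for j in range(n)})
        adj: dict[int, list[tuple[int, int]]] = {v: [] for v in rem}
        for k, (u, v) in enumerate(tree):
            adj[u].append((v, k))
            adj[v].append((u, k))
        removed = [False] * len(tree)
        degree = {v: len(adj[v]) for v in adj}
        leaves = [v for v in adj if degree[v] == 1]
        total = 0.0
        feasible = True
        for _ in range(len(tree)):
            v = leaves.pop()
            u, k = next((u, k) for u, k in adj[v] if not removed[k])
            f = rem[v]
            if f < -1e-12:
                feasible = False
                break
            row, col = (u, v) if u < m else (v, u)
            total += f * cost[row, col - m]
            removed[k] = True
            rem[v] = 0.0
            rem[u] -= f
            degree[u] -= 1
            degree[v] -= 1
            if degree[u] == 1:
                leaves.append(u)
        if feasible and total < best:
            best = total
    return float(best)
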