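"""Independent brute-force oracles for graph metrics.

Everything here is deliberately naive (Floyd–Warshall relaxation, explicit
path enumeration, neighbour-pair counting) and shares no code with the
package implementation.
"""

from itertools import combinations

import numpy as np


def floyd_warshall(A):
    n = len(A)
    d = np.full((n, n), np.inf)
    for i in range(n):
        d[i, i] = 0.0
    for i in range(n):
        for j in range(n):
            if A[i][j]:
                d[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def efficiency(A):
    n = len(A)
    d = floyd_warshall(A)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def clustering(A):
    n = len(A)
    vals = []
    for i in range(n):
        nbrs = [j for j in range(n) if A[i][j]]
        k = len(nbrs)
        if k < 2:
            vals.append(0.0)
            continue
        links = sum(1 for u, v in combinations(nbrs, 2) if A[u][v])
        vals.append(links / (k * (k - 1) / 2))
    return float(np.mean(vals))


def transitivity(A):
    n = len(A)
    triangles = sum(
        1 for i, j, k in combinations(range(n), 3) if A[i][j] and A[j][k] and A[i][k]
    )
    triples = 0
    for i in range(n):
        k = int(sum(A[i]))
        triples += k * (k - 1) // 2
    return 3.0 * triangles / triples if triples else 0.0


def edge_count(A):
    n = len(A)
    return sum(1 for i, j in combinations(range(n), 2) if A[i][j])


def long_edges(A, dist_mm, cutoff=75.0):
    n = len(A)
    return sum(1 for i, j in combinations(range(n), 2) if A[i][j] and dist_mm[i][j] > cutoff)


def _shortest_paths(A, dist, s, t):
    """All shortest s-t paths, by DFS along strictly distance-decreasing edges."""
    if not np.isfinite(dist[s][t]):
        return []
    paths = []

    def extend(u, path):
        if u == t:
            paths.append(path)
            return
        for v in range(len(A)):
            if A[u][v] and dist[v][t] == dist[u][t] - 1:
                extend(v, path + [v])

    extend(s, [s])
    return paths


def betweenness(A):
    """Fractional shortest-path credit, unordered pairs, endpoints excluded."""
    n = len(A)
    dist = floyd_warshall(A)
    b = np.zeros(n)
    for s, t in combinations(range(n), 2):
        paths = _shortest_paths(A, dist, s, t)
        if not paths:
            continue
        for path in paths:
            for v in path[1:-1]:
                b[v] += 1.0 / len(paths)
    return b


def random_graph(n, p, seed):
    rng = np.random.default_rng(seed)
    A = (rng.uniform(size=(n, n)) < p).astype(float)
    A = np.triu(A, 1)
    return A + A.T
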