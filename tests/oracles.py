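"""Independent brute-force reference implementations used only by tests.

Deliberately naive: triple-loop Floyd-Warshall, explicit shortest-path
enumeration, full eigendecomposition, fixed-point iteration, step-up FDR by
hand. These stay independent of the library code paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np


def floyd_warshall(adjacency) -> np.ndarray:
    A = np.asarray(adjacency)
    n = A.shape[0]
    D = np.full((n, n), np.inf)
    for i in range(n):
        D[i, i] = 0.0
    for i in range(n):
        for j in range(n):
            if A[i, j]:
                D[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def weighted_floyd_warshall(dist) -> np.ndarray:
    D = np.array(dist, dtype=float)
    n = D.shape[0]
    np.fill_diagonal(D, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def all_shortest_paths(adjacency, s, t, D=None) -> list[tuple[int, ...]]:
    """Enumerate every shortest s->t path by DFS."""
    A = np.asarray(adjacency)
    if D is None:
        D = floyd_warshall(A)
    if not np.isfinite(D[s, t]):
        return []
    paths = []

    def extend(path):
        node = path[-1]
        if node == t:
            paths.append(tuple(path))
            return
        for nxt in np.flatnonzero(A[node]):
            if D[s, node] + 1 + D[nxt, t] == D[s, t] and D[s, nxt] == D[s, node] + 1:
                extend(path + [nxt])

    extend([s])
    return paths


def betweenness_all(adjacency) -> np.ndarray:
    """Ordered-pair betweenness for every node by explicit path enumeration."""
    A = np.asarray(adjacency)
    n = A.shape[0]
    D = floyd_warshall(A)
    total = np.zeros(n)
    for k in range(n):
        for j in range(n):
            if k == j:
                continue
            paths = all_shortest_paths(A, k, j, D=D)
            if not paths:
                continue
            through = np.zeros(n)
            for p in paths:
                for node in p[1:-1]:
                    through[node] += 1
            contribution = through / len(paths)
            contribution[k] = contribution[j] = 0.0
            total += contribution
    return total


def betweenness(adjacency, i) -> float:
    return float(betweenness_all(adjacency)[i])


def global_efficiency(adjacency) -> float:
    D = floyd_warshall(adjacency)
    n = D.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(D[i, j]):
                total += 1.0 / D[i, j]
    return total / (n * (n - 1))


def nodal_efficiency(adjacency, i) -> float:
    D = floyd_warshall(adjacency)
    n = D.shape[0]
    return sum(
        1.0 / D[i, j] for j in range(n) if j != i and np.isfinite(D[i, j])
    ) / (n - 1)


def local_efficiency(adjacency, i) -> float:
    A = np.asarray(adjacency)
    nb = np.flatnonzero(A[i])
    if nb.size < 2:
        return 0.0
    return global_efficiency(A[np.ix_(nb, nb)])


def eigenvector_centrality(adjacency) -> np.ndarray:
    A = np.asarray(adjacency, dtype=float)
    w, V = np.linalg.eig(A)
    k = np.argmax(w.real)
    v = V[:, k].real
    v = v / np.linalg.norm(v)
    if v.sum() < 0:
        v = -v
    return v


def pagerank(adjacency, d=0.85, tol=1e-14, max_iter=100000) -> np.ndarray:
    A = np.asarray(adjacency, dtype=float)
    deg = A.sum(axis=1)
    n = A.shape[0]
    r = np.ones(n)
    for _ in range(max_iter):
        r_new = (1 - d) + d * A @ (r / deg)
        if np.max(np.abs(r_new - r)) < tol:
            return r_new
        r = r_new
    raise RuntimeError("pagerank iteration did not converge")


def pearson(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm @ ym) / np.sqrt((xm @ xm) * (ym @ ym)))


def bh_stepup(p, q=0.05):
    """Step-up BH by the textbook recipe: flags and monotone q-values."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    thresh = q * (np.arange(1, m + 1)) / m
    below = np.flatnonzero(sorted_p <= thresh)
    flags = np.zeros(m, bool)
    if below.size:
        flags[order[: below.max() + 1]] = True
    qvals_sorted = sorted_p * m / np.arange(1, m + 1)
    for i in range(m - 2, -1, -1):
        qvals_sorted[i] = min(qvals_sorted[i], qvals_sorted[i + 1])
    qvals = np.empty(m)
    qvals[order] = np.minimum(qvals_sorted, 1.0)
    return qvals, flags


def spanning_trees(n, edges):
    """All spanning trees (as frozensets of edges) of a small graph."""
    trees = []
    for combo in itertools.combinations(edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        ok = True
        for i, j in combo:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[rj] = ri
        if ok:
            trees.append(frozenset(combo))
    return trees


def connected_random_graph(rng, n, p=0.35):
    """Random Erdos-Renyi graph conditioned (by redraw) on connectivity."""
    while True:
        A = np.zeros((n, n), dtype=int)
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p:
                    A[i, j] = A[j, i] = 1
        if np.all(np.isfinite(floyd_warshall(A)[0])):
            return A
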