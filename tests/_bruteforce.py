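"""Deliberately naive reference implementations of every graph metric.

Independent of the package's vectorized engine: distances come from
Floyd–Warshall, betweenness from explicit enumeration of all shortest
paths, clustering from triangle counting over neighbor pairs.  Used as
the oracle in equivalence tests; kept simple enough to verify by eye.
"""

from __future__ import annotations

import itertools

import numpy as np

INF = float("inf")


def floyd_warshall(A) -> np.ndarray:
    A = np.asarray(A)
    n = A.shape[0]
    D = np.full((n, n), INF)
    for i in range(n):
        D[i, i] = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and A[i, j]:
                D[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def clustering(A) -> tuple[list[float], float]:
    A = np.asarray(A)
    n = A.shape[0]
    Ci = []
    for i in range(n):
        nbrs = [j for j in range(n) if A[i, j]]
        k = len(nbrs)
        if k < 2:
            Ci.append(0.0)
            continue
        links = sum(1 for a, b in itertools.combinations(nbrs, 2)
                    if A[a, b])
        Ci.append(2.0 * links / (k * (k - 1)))
    return Ci, sum(Ci) / n


def harmonic_path_length(A) -> float:
    D = floyd_warshall(A)
    n = D.shape[0]
    total_inv = sum(1.0 / D[i, j] for i in range(n) for j in range(n)
                    if i != j and D[i, j] < INF)
    if total_inv == 0:
        raise ValueError("no finite distances")
    return n * (n - 1) / total_inv


def global_eff(A) -> float:
    D = floyd_warshall(A)
    n = D.shape[0]
    if n < 2:
        return 0.0
    return sum(1.0 / D[i, j] for i in range(n) for j in range(n)
               if i != j and D[i, j] < INF) / (n * (n - 1))


def local_eff(A) -> float:
    A = np.asarray(A)
    n = A.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if A[i, j]]
        if len(nbrs) < 2:
            continue
        sub = A[np.ix_(nbrs, nbrs)]
        total += global_eff(sub)
    return total / n


def nodal_efficiency(A) -> list[float]:
    D = floyd_warshall(A)
    n = D.shape[0]
    return [sum(1.0 / D[i, j] for j in range(n)
                if j != i and D[i, j] < INF) / (n - 1) for i in range(n)]


def _all_shortest_paths(A, s, t, D):
    """Every shortest s->t path, by depth-first extension."""
    if D[s, t] == INF:
        return []
    n = A.shape[0]
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(list(path))
            return
        for v in range(n):
            if A[u, v] and D[s, v] == D[s, u] + 1 and D[v, t] == D[u, t] - 1:
                extend(path + [v])

    extend([s])
    return paths


def betweenness(A) -> list[float]:
    """b_i = sum over unordered pairs s != i != t of the fraction of
    shortest s-t paths passing through i."""
    A = np.asarray(A)
    n = A.shape[0]
    D = floyd_warshall(A)
    b = [0.0] * n
    for s, t in itertools.combinations(range(n), 2):
        paths = _all_shortest_paths(A, s, t, D)
        if not paths:
            continue
        for i in range(n):
            if i in (s, t):
                continue
            through = sum(1 for p in paths if i in p)
            b[i] += through / len(paths)
    return b


def degrees(A) -> list[int]:
    return [int(x) for x in np.asarray(A).sum(axis=1)]


def connected(A) -> bool:
    D = floyd_warshall(A)
    return bool(np.isfinite(D).all())


def all_graphs(n):
    """Every labeled simple graph on n nodes (as adjacency arrays)."""
    pairs = list(itertools.combinations(range(n), 2))
    for bits in itertools.product((0, 1), repeat=len(pairs)):
        A = np.zeros((n, n))
        for (i, j), b in zip(pairs, bits):
            A[i, j] = A[j, i] = b
        yield A
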