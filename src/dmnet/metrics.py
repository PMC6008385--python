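"""Topology metrics on sparsity-thresholded binary graphs.

A subject-level connectivity matrix is reduced to a family of undirected
binary graphs by keeping, at each sparsity level ``Sp``, the
``K = round(Sp * N(N-1)/2)`` strongest edges.  On each graph the module
computes the standard small-world and efficiency metrics:

* clustering coefficient ``Cp`` (mean of nodal ``Ci``),
* characteristic path length ``Lp`` as the *harmonic mean* distance over
  all ordered pairs (finite on disconnected graphs; ``Lp * Eglob == 1``),
* global and local efficiency ``Eglob`` / ``Eloc``,
* nodal degree, (unnormalized) betweenness and nodal efficiency,
* largest connected-component size,

plus the normalized small-world parameters ``gamma = Cp/Cp_rand``,
``lambda = Lp/Lp_rand`` and ``sigma = gamma/lambda`` against an ensemble
of degree-preserving (Maslov–Sneppen) rewired random networks.

Everything is vectorized over plain numpy adjacency matrices: the study
design evaluates 46 sparsity levels x ~100 subjects x replicate cohorts,
so per-graph overhead matters.  All shortest paths come from a batched
boolean BFS; betweenness uses a level-synchronous formulation of Brandes'
dependency accumulation that runs for all source nodes simultaneously.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_GRID",
    "BinaryGraph",
    "MetricCurves",
    "binarize_at_sparsity",
    "clustering_coefficient",
    "path_length_harmonic",
    "global_efficiency",
    "local_efficiency",
    "nodal_metrics",
    "largest_component_size",
    "rewire_preserving_degree",
    "small_world_parameters",
    "metric_curves",
    "auc",
    "shortest_path_lengths",
]

#: Default sparsity grid: 0.05 ... 0.50 in steps of 0.01 (46 levels).
DEFAULT_GRID = np.round(np.arange(5, 51) * 0.01, 2)

GLOBAL_METRICS = ("cp", "lp", "gamma", "lambda", "sigma", "eglob", "eloc",
                  "largest_component")
NODAL_METRICS = ("degree", "betweenness", "efficiency", "clustering")


@dataclass
class BinaryGraph:
    """Undirected binary graph: symmetric 0/1 adjacency with zero diagonal."""

    adjacency: np.ndarray
    labels: Sequence[str] | None = None
    sparsity: float | None = None

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(A, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        self.adjacency = A.astype(np.uint8)
        if self.labels is None:
            self.labels = [str(i) for i in range(A.shape[0])]
        elif len(self.labels) != A.shape[0]:
            raise ValueError("label count does not match adjacency size")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def to_networkx(self):
        import networkx as nx

        G = nx.from_numpy_array(self.adjacency)
        return nx.relabel_nodes(G, dict(enumerate(self.labels)))


def _as_adjacency(G) -> np.ndarray:
    if isinstance(G, BinaryGraph):
        return G.adjacency.astype(np.float64)
    A = np.asarray(G, dtype=np.float64)
    return A


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------

def edge_count_at_sparsity(n_nodes: int, sp: float) -> int:
    """K = round(Sp * N(N-1)/2), rounding half away from zero."""
    m_max = n_nodes * (n_nodes - 1) / 2
    return int(np.floor(sp * m_max + 0.5))


def binarize_at_sparsity(C, sp: float, *, labels=None,
                         rank: str = "signed") -> BinaryGraph:
    """Keep the K strongest edges of a connectivity matrix.

    Parameters
    ----------
    C : array-like or ConnectivityMatrix
        Symmetric correlation matrix; the diagonal is ignored.
    sp : float
        Target sparsity in (0, 1]: fraction of retained edges relative to
        the N(N-1)/2 possible edges.
    rank : {"signed", "abs"}
        Rank candidate edges by signed correlation (default, strongest
        positive first) or by absolute value.  Ties are broken by
        lexicographic node-pair order so thresholding is deterministic.
    """
    values = getattr(C, "values", C)
    if labels is None:
        labels = getattr(C, "labels", None)
    M = np.asarray(values, dtype=np.float64)
    n = M.shape[0]
    if not 0 < sp <= 1:
        raise ValueError(f"sparsity must be in (0, 1], got {sp}")
    K = edge_count_at_sparsity(n, sp)
    if K == 0:
        raise ValueError(f"sparsity {sp} yields zero edges for n={n}")
    iu, ju = np.triu_indices(n, k=1)
    w = M[iu, ju]
    if rank == "abs":
        w = np.abs(w)
    elif rank != "signed":
        raise ValueError(f"unknown rank mode {rank!r}")
    # sort by weight descending, then (i, j) ascending
    order = np.lexsort((ju, iu, -w))
    keep = order[:K]
    A = np.zeros((n, n), dtype=np.uint8)
    A[iu[keep], ju[keep]] = 1
    A = A | A.T
    return BinaryGraph(A, labels=labels, sparsity=sp)


# ---------------------------------------------------------------------------
# distances (batched BFS)
# ---------------------------------------------------------------------------

def shortest_path_lengths(A: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path lengths of one or a stack of binary graphs.

    ``A`` has shape ``(..., n, n)``; the result has the same shape with
    ``inf`` marking disconnected pairs.  Implemented as a level-synchronous
    BFS using matrix products, which is exact for unweighted graphs.
    """
    A = np.asarray(A, dtype=np.float64)
    n = A.shape[-1]
    eye = np.eye(n, dtype=bool)
    reach = np.broadcast_to(eye, A.shape).copy()
    frontier = reach.copy()
    D = np.where(reach, 0.0, np.inf)
    d = 0
    while True:
        d += 1
        nxt = (frontier.astype(np.float64) @ A) > 0
        new = nxt & ~reach
        if not new.any():
            break
        D[new] = d
        reach |= new
        frontier = new
    return D


def _inverse_distances(D: np.ndarray) -> np.ndarray:
    n = D.shape[-1]
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D) & (D > 0), 1.0 / D, 0.0)
    return inv


# ---------------------------------------------------------------------------
# global metrics
# ---------------------------------------------------------------------------

def clustering_coefficient(G) -> tuple[np.ndarray, float]:
    """Nodal clustering ``Ci`` and network average ``Cp``.

    ``Ci`` is the fraction of realized connections among node *i*'s
    neighbors; nodes of degree < 2 contribute ``Ci = 0``.
    """
    A = _as_adjacency(G)
    k = A.sum(axis=-1)
    # (A^3)_ii / 2 = number of edges among neighbors of i
    tri = np.einsum("...ij,...jk,...ki->...i", A, A, A) / 2.0
    denom = k * (k - 1) / 2.0
    Ci = np.divide(tri, denom, out=np.zeros_like(tri), where=denom > 0)
    return Ci, float(Ci.mean(axis=-1)) if Ci.ndim == 1 else Ci.mean(axis=-1)


def global_efficiency(G, D: np.ndarray | None = None) -> float:
    """Mean inverse shortest-path length over ordered pairs (0 for empty)."""
    A = _as_adjacency(G)
    n = A.shape[-1]
    if D is None:
        D = shortest_path_lengths(A)
    inv = _inverse_distances(D)
    return float(inv.sum() / (n * (n - 1)))


def path_length_harmonic(G, D: np.ndarray | None = None) -> float:
    """Harmonic-mean characteristic path length.

    ``Lp = n(n-1) / sum_{i!=j} 1/d_ij`` with ``1/inf = 0``, so disconnected
    pairs shorten nothing and ``Lp`` stays finite whenever at least one
    finite distance exists.  Satisfies ``Lp * Eglob == 1``.
    """
    eglob = global_efficiency(G, D)
    if eglob == 0.0:
        raise ValueError("graph has no finite distances; Lp undefined")
    return 1.0 / eglob


def local_efficiency(G, D: np.ndarray | None = None) -> float:
    """Mean, over nodes, of the global efficiency of each node's
    neighbor-induced subgraph (0 for neighborhoods of < 2 nodes)."""
    A = _as_adjacency(G)
    n = A.shape[-1]
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(A[i] > 0)
        if nbrs.size < 2:
            continue
        sub = A[np.ix_(nbrs, nbrs)]
        total += global_efficiency(sub)
    return total / n


def largest_component_size(G, D: np.ndarray | None = None) -> int:
    """Node count of the largest connected component (>= 1 by convention:
    an isolated node is a size-1 component, so an empty graph reports 1)."""
    A = _as_adjacency(G)
    if D is None:
        D = shortest_path_lengths(A)
    return int(np.isfinite(D).sum(axis=-1).max())


# ---------------------------------------------------------------------------
# nodal metrics
# ---------------------------------------------------------------------------

def _betweenness_from_distances(A: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness via level-synchronous Brandes accumulation.

    ``b_i = sum over unordered pairs s != i != t of sigma_st(i)/sigma_st``
    where sigma counts shortest paths.  All sources are processed at once
    (and ``A`` may carry leading batch axes): shortest-path counts grow
    level by level through masked matrix products, dependencies flow back
    the same way.
    """
    n = A.shape[-1]
    finite = np.isfinite(D)
    dmax = int(D[finite].max()) if finite.any() else 0
    levels = [D == d for d in range(dmax + 1)]
    # sigma[..., s, v]: number of shortest s->v paths
    sigma = np.broadcast_to(np.eye(n), A.shape).copy()
    for d in range(1, dmax + 1):
        sigma = sigma + ((sigma * levels[d - 1]) @ A) * levels[d]
    delta = np.zeros_like(sigma)
    for d in range(dmax, 0, -1):
        ratio = np.divide(1.0 + delta, sigma,
                          out=np.zeros_like(delta), where=levels[d])
        delta = delta + (ratio @ A) * sigma * levels[d - 1]
    diag = np.broadcast_to(np.eye(n, dtype=bool), delta.shape)
    delta = np.where(diag, 0.0, delta)
    return delta.sum(axis=-2) / 2.0


def nodal_metrics(G, D: np.ndarray | None = None) -> pd.DataFrame:
    """Per-node degree, betweenness and nodal efficiency.

    Betweenness is the raw sum of pair fractions (not divided by the
    number of pairs); nodal efficiency is ``mean_j 1/d_ij`` over the other
    ``n-1`` nodes.
    """
    A = _as_adjacency(G)
    n = A.shape[-1]
    if D is None:
        D = shortest_path_lengths(A)
    inv = _inverse_distances(D)
    labels = G.labels if isinstance(G, BinaryGraph) else list(range(n))
    return pd.DataFrame(
        {
            "degree": A.sum(axis=1).astype(float),
            "betweenness": _betweenness_from_distances(A, D),
            "efficiency": inv.sum(axis=1) / (n - 1),
        },
        index=pd.Index(labels, name="node"),
    )


# ---------------------------------------------------------------------------
# degree-preserving null model
# ---------------------------------------------------------------------------

def _edge_array(A: np.ndarray) -> np.ndarray:
    iu, ju = np.nonzero(np.triu(A, k=1))
    return np.stack([iu, ju], axis=1)


def rewire_preserving_degree(G, swaps_per_edge: int = 100,
                             seed=None) -> BinaryGraph:
    """Maslov–Sneppen double-edge-swap randomization.

    Attempts ``swaps_per_edge * m`` swaps; proposals creating self-loops,
    multi-edges or touching fewer than 4 distinct nodes are rejected.  The
    degree sequence is exactly preserved.  If no proposal succeeds within
    the attempt budget the current (possibly unchanged) graph is returned
    with a warning.
    """
    A = _as_adjacency(G).astype(bool)
    labels = G.labels if isinstance(G, BinaryGraph) else None
    edges = _edge_array(A)
    m = len(edges)
    if m < 2:
        raise ValueError("need at least 2 edges to rewire")
    rng = np.random.default_rng(seed)
    n_attempts = swaps_per_edge * m
    pairs = rng.integers(0, m, size=(n_attempts, 2))
    flips = rng.random(n_attempts) < 0.5
    successes = 0
    ed = edges  # int array, mutated in place
    for t in range(n_attempts):
        e1, e2 = pairs[t]
        if e1 == e2:
            continue
        a, b = ed[e1]
        c, d = ed[e2]
        if flips[t]:
            c, d = d, c
        # propose (a,b),(c,d) -> (a,d),(c,b)
        if a == c or a == d or b == c or b == d:
            continue
        if A[a, d] or A[c, b]:
            continue
        A[a, b] = A[b, a] = False
        A[c, d] = A[d, c] = False
        A[a, d] = A[d, a] = True
        A[c, b] = A[b, c] = True
        ed[e1] = (a, d) if a < d else (d, a)
        ed[e2] = (c, b) if c < b else (b, c)
        successes += 1
    if successes == 0 and swaps_per_edge > 0:
        warnings.warn(
            "no valid degree-preserving swap found within the attempt "
            "budget; returning the graph unchanged", RuntimeWarning)
    return BinaryGraph(A.astype(np.uint8), labels=labels,
                       sparsity=G.sparsity if isinstance(G, BinaryGraph) else None)


def _rewire_ensemble(A: np.ndarray, n_random: int, swaps_per_edge: int,
                     rng: np.random.Generator, block: int = 16) -> np.ndarray:
    """Stack of ``n_random`` degree-preserving rewirings of ``A``.

    Vectorized across ensemble members *and* across blocks of swap
    proposals: each step draws ``block`` disjoint edge pairs per member
    and applies every proposal that is valid against the pre-block state
    (self-loops, multi-edges, shared endpoints and within-block creation
    collisions are rejected; rejections against a stale adjacency are
    merely conservative).  Every accepted double swap preserves the
    degree sequence exactly, so the blocked chain remains a valid
    Maslov–Sneppen randomization.
    """
    A = np.asarray(A, dtype=bool)
    n = A.shape[0]
    base_edges = _edge_array(A)
    m = len(base_edges)
    R = n_random
    Aens = np.broadcast_to(A, (R,) + A.shape).copy()
    E = np.broadcast_to(base_edges, (R, m, 2)).copy()
    if m < 2 or swaps_per_edge == 0:
        return Aens
    B = max(1, min(block, m // 2))
    n_steps = int(np.ceil(swaps_per_edge * m / B))
    r_col = np.arange(R)[:, np.newaxis]
    sentinel = n * n + np.arange(2 * B)  # per-column unique, never a real key
    for _ in range(n_steps):
        # 2B distinct edge indices per member, paired up
        idx = np.argpartition(rng.random((R, m)), 2 * B - 1,
                              axis=1)[:, :2 * B]
        e1, e2 = idx[:, :B], idx[:, B:]
        a = E[r_col, e1, 0]
        b = E[r_col, e1, 1]
        c0 = E[r_col, e2, 0]
        d0 = E[r_col, e2, 1]
        flip = rng.random((R, B)) < 0.5
        c = np.where(flip, d0, c0)
        d = np.where(flip, c0, d0)
        ok = ((a != c) & (a != d) & (b != c) & (b != d)
              & ~Aens[r_col, a, d] & ~Aens[r_col, c, b])
        # reject proposals whose *created* edges collide within the block
        k1 = np.minimum(a, d) * n + np.maximum(a, d)
        k2 = np.minimum(c, b) * n + np.maximum(c, b)
        keys = np.concatenate([k1, k2], axis=1)
        okok = np.concatenate([ok, ok], axis=1)
        keys = np.where(okok, keys, sentinel)
        order = np.argsort(keys, axis=1)
        skeys = np.take_along_axis(keys, order, axis=1)
        dup_s = np.zeros_like(okok)
        eq = skeys[:, 1:] == skeys[:, :-1]
        dup_s[:, 1:] |= eq
        dup_s[:, :-1] |= eq
        dup = np.zeros_like(okok)
        np.put_along_axis(dup, order, dup_s, axis=1)
        ok &= ~(dup[:, :B] | dup[:, B:])
        if not ok.any():
            continue
        rr, pp = np.nonzero(ok)
        aa, bb = a[rr, pp], b[rr, pp]
        cc, dd = c[rr, pp], d[rr, pp]
        Aens[rr, aa, bb] = Aens[rr, bb, aa] = False
        Aens[rr, cc, dd] = Aens[rr, dd, cc] = False
        Aens[rr, aa, dd] = Aens[rr, dd, aa] = True
        Aens[rr, cc, bb] = Aens[rr, bb, cc] = True
        E[rr, e1[rr, pp], 0] = np.minimum(aa, dd)
        E[rr, e1[rr, pp], 1] = np.maximum(aa, dd)
        E[rr, e2[rr, pp], 0] = np.minimum(cc, bb)
        E[rr, e2[rr, pp], 1] = np.maximum(cc, bb)
    return Aens


def _ensemble_cp_lp(Aens: np.ndarray) -> tuple[float, float]:
    """Mean Cp and harmonic Lp over a stacked graph ensemble."""
    Af = Aens.astype(np.float64)
    n = Af.shape[-1]
    Ci, _ = clustering_coefficient(Af)
    cp = float(Ci.mean(axis=-1).mean())
    D = shortest_path_lengths(Af)
    inv = _inverse_distances(D)
    eglob = inv.sum(axis=(-2, -1)) / (n * (n - 1))
    with np.errstate(divide="ignore"):
        lp = np.where(eglob > 0, 1.0 / eglob, np.nan)
    return cp, float(np.nanmean(lp))


def small_world_parameters(G, n_random: int = 1000, seed=None,
                           swaps_per_edge: int = 100) -> dict[str, float]:
    """Normalized small-world parameters against a degree-matched null.

    Returns ``{"gamma", "lambda", "sigma", "cp_rand", "lp_rand"}`` where
    ``gamma = Cp / mean(Cp_rand)``, ``lambda = Lp / mean(Lp_rand)`` and
    ``sigma = gamma / lambda``.  ``gamma`` is reported as NaN (with a
    warning) when the random ensemble has zero clustering.
    """
    A = _as_adjacency(G)
    if A.sum() == 0:
        raise ValueError("graph has no edges")
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    rng = np.random.default_rng(seed)
    _, cp = clustering_coefficient(A)
    D = shortest_path_lengths(A)
    lp = path_length_harmonic(A, D)
    Aens = _rewire_ensemble(A, n_random, swaps_per_edge, rng)
    cp_rand, lp_rand = _ensemble_cp_lp(Aens)
    if cp_rand == 0.0:
        warnings.warn("random ensemble has zero clustering; gamma undefined",
                      RuntimeWarning)
        gamma = np.nan
    else:
        gamma = cp / cp_rand
    lam = lp / lp_rand
    sigma = gamma / lam
    return {"gamma": gamma, "lambda": lam, "sigma": sigma,
            "cp_rand": cp_rand, "lp_rand": lp_rand}


# ---------------------------------------------------------------------------
# curves over the sparsity grid and AUC
# ---------------------------------------------------------------------------

@dataclass
class MetricCurves:
    """Global and nodal metric values across a sparsity grid."""

    grid: np.ndarray
    global_metrics: pd.DataFrame          # index: sparsity, columns: metric
    nodal: dict[str, pd.DataFrame]        # metric -> (sparsity x node)

    def global_auc(self) -> pd.Series:
        """AUC of every global metric curve over the grid.

        Metrics that were not computed (all-missing curves, e.g. sigma
        when the random null was skipped) summarize to NaN.
        """
        vals = _auc_columns(self.global_metrics.to_numpy(), self.grid)
        return pd.Series(vals, index=self.global_metrics.columns,
                         name="auc")

    def nodal_auc(self) -> pd.DataFrame:
        """AUC per node per nodal metric (nodes x metrics)."""
        out = {}
        for metric, df in self.nodal.items():
            out[metric] = pd.Series(_auc_columns(df.to_numpy(), self.grid),
                                    index=df.columns)
        return pd.DataFrame(out).rename_axis(index="node")

    def to_tidy(self) -> pd.DataFrame:
        """Long-format table (metric, sparsity, node, value); global rows
        carry node = ''. Round-trips through CSV."""
        rows = [
            self.global_metrics.rename_axis(index="sparsity")
            .reset_index()
            .melt(id_vars="sparsity", var_name="metric", value_name="value")
            .assign(node="")
        ]
        for metric, df in self.nodal.items():
            rows.append(
                df.rename_axis(index="sparsity").reset_index()
                .melt(id_vars="sparsity", var_name="node", value_name="value")
                .assign(metric=metric)
            )
        return pd.concat(rows, ignore_index=True)[
            ["metric", "sparsity", "node", "value"]]


def _local_efficiency_stack(A: np.ndarray) -> np.ndarray:
    """Local efficiency for a stack of graphs (S, n, n) in one pass.

    Every node's neighbor-induced subgraph is gathered into a common
    zero-padded (kmax, kmax) frame; padding rows stay disconnected so
    they contribute nothing, and each subgraph's efficiency divides by
    its true size.  Nodes of degree < 2 contribute 0.
    """
    A = np.asarray(A, dtype=np.float64)
    S, n, _ = A.shape
    k = A.sum(axis=-1).astype(int)                      # (S, n)
    kmax = int(k.max())
    if kmax < 2:
        return np.zeros(S)
    order = np.argsort(-A, axis=-1, kind="stable")      # neighbors first
    nbr = order[..., :kmax]                             # (S, n, kmax)
    valid = np.arange(kmax) < k[..., np.newaxis]        # (S, n, kmax)
    s_idx = np.arange(S)[:, None, None, None]
    sub = A[s_idx, nbr[..., :, None], nbr[..., None, :]]
    mask = valid[..., :, None] & valid[..., None, :]
    sub = sub * mask
    D = shortest_path_lengths(sub.reshape(S * n, kmax, kmax))
    inv = _inverse_distances(D).sum(axis=(-2, -1)).reshape(S, n)
    m = k.astype(float)
    denom = m * (m - 1)
    eff = np.divide(inv, denom, out=np.zeros_like(inv), where=denom > 0)
    return eff.mean(axis=-1)


def _binarize_stack(M: np.ndarray, grid: np.ndarray,
                    rank: str) -> np.ndarray:
    """Adjacency stack (S, n, n): one thresholded graph per grid level.

    Edges are ranked once; level ``s`` keeps the top ``K(grid[s])``.
    """
    n = M.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = M[iu, ju]
    if rank == "abs":
        w = np.abs(w)
    elif rank != "signed":
        raise ValueError(f"unknown rank mode {rank!r}")
    order = np.lexsort((ju, iu, -w))
    ranks = np.empty(len(w), dtype=int)
    ranks[order] = np.arange(len(w))
    Ks = np.array([edge_count_at_sparsity(n, sp) for sp in grid])
    if np.any(Ks == 0):
        raise ValueError("grid contains a sparsity level with zero edges")
    keep = ranks[np.newaxis, :] < Ks[:, np.newaxis]
    A = np.zeros((len(grid), n, n))
    A[:, iu, ju] = keep
    return A + A.transpose(0, 2, 1)


def metric_curves(C, grid: np.ndarray | None = None, *, n_random: int = 100,
                  seed=None, swaps_per_edge: int = 100,
                  rank: str = "signed", include_betweenness: bool = True,
                  include_eloc: bool = True) -> MetricCurves:
    """Compute all global and nodal metrics at every sparsity level.

    ``n_random = 0`` skips the random-network normalization (gamma, lambda
    and sigma are reported as NaN), which is much faster when only raw
    metrics are needed; ``include_betweenness`` / ``include_eloc`` skip
    the two costliest metrics the same way.  All raw metrics are computed
    on the whole graph stack at once.  Deterministic given ``seed``.
    """
    if grid is None:
        grid = DEFAULT_GRID
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 1 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    if np.any((grid <= 0) | (grid > 1)):
        raise ValueError("grid values must lie in (0, 1]")
    values = np.asarray(getattr(C, "values", C), dtype=np.float64)
    labels = getattr(C, "labels", None)
    n = values.shape[0]
    if labels is None:
        labels = [str(i) for i in range(n)]

    A = _binarize_stack(values, grid, rank)          # (S, n, n)
    D = shortest_path_lengths(A)
    inv = _inverse_distances(D)
    k = A.sum(axis=-1)
    tri = np.einsum("sij,sjk,ski->si", A, A, A) / 2.0
    denom = k * (k - 1) / 2.0
    Ci = np.divide(tri, denom, out=np.zeros_like(tri), where=denom > 0)
    eglob = inv.sum(axis=(-2, -1)) / (n * (n - 1))
    with np.errstate(divide="ignore"):
        lp = np.where(eglob > 0, 1.0 / eglob, np.nan)
    lcc = np.isfinite(D).sum(axis=-1).max(axis=-1)

    S = len(grid)
    eloc = _local_efficiency_stack(A) if include_eloc else np.full(S, np.nan)
    betw = (_betweenness_from_distances(A, D) if include_betweenness
            else np.full((S, n), np.nan))
    gamma = np.full(S, np.nan)
    lam = np.full(S, np.nan)
    sigma_sw = np.full(S, np.nan)
    if n_random > 0:
        ss = (seed if isinstance(seed, np.random.SeedSequence)
              else np.random.SeedSequence(seed))
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            for s, sp_seed in enumerate(ss.spawn(S)):
                sw = small_world_parameters(A[s], n_random=n_random,
                                            seed=sp_seed,
                                            swaps_per_edge=swaps_per_edge)
                gamma[s], lam[s] = sw["gamma"], sw["lambda"]
                sigma_sw[s] = sw["sigma"]
        if caught:
            warnings.warn(f"{len(caught)} sparsity level(s) reported "
                          f"degenerate null ensembles (first: "
                          f"{caught[0].message})", RuntimeWarning)

    idx = pd.Index(grid, name="sparsity")
    global_df = pd.DataFrame(
        {"cp": Ci.mean(axis=-1), "lp": lp, "gamma": gamma, "lambda": lam,
         "sigma": sigma_sw, "eglob": eglob, "eloc": eloc,
         "largest_component": lcc.astype(float)}, index=idx)
    nodal = {
        "degree": pd.DataFrame(k, index=idx, columns=labels),
        "betweenness": pd.DataFrame(betw, index=idx, columns=labels),
        "efficiency": pd.DataFrame(inv.sum(axis=-1) / (n - 1), index=idx,
                                   columns=labels),
        "clustering": pd.DataFrame(Ci, index=idx, columns=labels),
    }
    return MetricCurves(grid=grid, global_metrics=global_df, nodal=nodal)


def _auc_columns(arr: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Column-wise trapezoidal AUC with NaN tolerance (NaN-free columns
    integrate in one vectorized pass; others fall back per column)."""
    out = np.empty(arr.shape[1])
    clean = np.isfinite(arr).all(axis=0)
    if clean.any():
        out[clean] = np.trapezoid(arr[:, clean], grid, axis=0)
    for j in np.flatnonzero(~clean):
        out[j] = _auc_or_nan(arr[:, j], grid)
    return out


def _auc_or_nan(curve, grid) -> float:
    y = np.asarray(curve, dtype=float)
    if np.isfinite(y).sum() < 2:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return auc(curve, grid)


def auc(curve, grid) -> float:
    """Trapezoidal area under a metric-vs-sparsity curve.

    Grid points where the curve is missing (NaN) are dropped pairwise with
    a warning; fewer than two finite points is an error.  For a constant
    curve ``c`` the result is ``c * (grid span)``; exact for linear curves.
    """
    y = np.asarray(curve, dtype=float)
    x = np.asarray(grid, dtype=float)
    if y.shape != x.shape or y.ndim != 1 or len(y) < 2:
        raise ValueError("curve and grid must be 1-D of equal length >= 2")
    finite = np.isfinite(y)
    if finite.sum() < 2:
        raise ValueError("fewer than 2 finite points; AUC undefined")
    if not finite.all():
        warnings.warn(f"dropping {int((~finite).sum())} missing curve "
                      "points before AUC", RuntimeWarning)
        y, x = y[finite], x[finite]
    return float(np.trapezoid(y, x))
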