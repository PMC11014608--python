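"""Exact KNN search, both SNN constructions, and Louvain variants.

The two mainstream single-cell toolkits build their cell-cell graphs and run
Louvain differently, and those differences are the point of this module:

* SNN construction is either Jaccard-of-neighborhoods with pruning
  (:func:`snn_jaccard_prune`, default prune 1/15) or the plain undirected
  union of the directed KNN edges (:func:`snn_undirected_union`).
* :func:`louvain` implements two move-phase / quality-score variants.
  ``local_moves_scaled`` considers only the communities of a node's
  neighbors as move targets, caps the number of sweeps, and uses a quality
  normalized by the total network weight:

      Q = sum_c [ w_c - gamma * K_c^2 / (4 W) ] / W

  ``all_moves_expected`` considers every community plus one empty community
  and penalizes by the expected within-community weight under the
  configuration null, unnormalized:

      Q = sum_c [ w_c - gamma * K_c^2 / (4 W) ]

  with w_c the within-community weight (each edge once, self-loops
  included), K_c the summed node strengths, and W the total weight.  These
  exact forms are documented constants of this package.

Neighborhood sets include the self node (so a KNN list of length k holds
k - 1 true neighbors); a flag excludes self for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .preprocess import PCAResult

__all__ = [
    "NeighborGraphs",
    "Clustering",
    "knn_exact",
    "snn_jaccard_prune",
    "snn_undirected_union",
    "louvain",
    "partition_quality",
]


@dataclass
class NeighborGraphs:
    """Directed KNN neighbor lists and/or a weighted undirected SNN graph."""

    knn: np.ndarray = None          # n x k neighbor indices, self first
    snn: sp.csr_matrix = None       # symmetric weighted adjacency
    k: int = None
    prune_threshold: float = None
    construction: str = None        # "jaccard_prune" | "undirected_union"
    include_self: bool = True

    @property
    def n_cells(self):
        if self.knn is not None:
            return self.knn.shape[0]
        return self.snn.shape[0]


@dataclass
class Clustering:
    """A partition of cells with the quality score that produced it."""

    labels: np.ndarray
    resolution: float
    quality: float
    variant: str
    seed: int
    n_iterations: int = 0
    provenance: dict = field(default_factory=dict)


def knn_exact(pca: PCAResult, k: int = 20, include_self: bool = True) -> NeighborGraphs:
    """Exact k-nearest neighbors in PC space (Euclidean).

    Ties are broken by lower cell index; the self node is always first in
    each list (when ``include_self``; otherwise lists hold k non-self
    neighbors).
    """
    E = np.asarray(pca.embeddings, dtype=float)
    n = E.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds {n} cells")
    sq = (E ** 2).sum(axis=1)
    D = sq[:, None] + sq[None, :] - 2.0 * (E @ E.T)
    np.maximum(D, 0.0, out=D)
    if include_self:
        np.fill_diagonal(D, -1.0)  # force self first even under ties
        order = np.argsort(D, axis=1, kind="stable")  # stable -> lower index wins
        knn = order[:, :k]
    else:
        if k > n - 1:
            raise ValueError(f"k={k} exceeds {n - 1} non-self cells")
        np.fill_diagonal(D, np.inf)
        order = np.argsort(D, axis=1, kind="stable")
        knn = order[:, :k]
    return NeighborGraphs(knn=knn, k=k, include_self=include_self)


def _membership(g: NeighborGraphs) -> sp.csr_matrix:
    n, k = g.knn.shape
    rows = np.repeat(np.arange(n), k)
    return sp.csr_matrix(
        (np.ones(n * k), (rows, g.knn.ravel())), shape=(n, n)
    )


def snn_jaccard_prune(g: NeighborGraphs, prune: float = 1 / 15) -> NeighborGraphs:
    """SNN by Jaccard overlap of KNN neighborhoods, pruned below ``prune``.

    For every pair of cells sharing at least one KNN member the weight is
    ``|N(i) & N(j)| / |N(i) | N(j)|``; weights strictly below ``prune`` are
    set to zero.  Symmetric by construction.
    """
    if g.knn is None:
        raise ValueError("KNN graph required")
    A = _membership(g)
    inter = (A @ A.T).tocoo()
    k = g.k
    keep = inter.row != inter.col
    r, c, i = inter.row[keep], inter.col[keep], inter.data[keep]
    w = i / (2 * k - i)  # both sets have exactly k members
    mask = w >= prune
    snn = sp.csr_matrix((w[mask], (r[mask], c[mask])), shape=inter.shape)
    return NeighborGraphs(knn=g.knn, snn=snn, k=k, prune_threshold=prune,
                          construction="jaccard_prune",
                          include_self=g.include_self)


def snn_undirected_union(g: NeighborGraphs) -> NeighborGraphs:
    """SNN as the undirected union of directed KNN edges (self excluded)."""
    if g.knn is None:
        raise ValueError("KNN graph required")
    A = _membership(g).tolil()
    A.setdiag(0)
    A = A.tocsr()
    U = A + A.T
    U.data = np.ones_like(U.data)
    U.eliminate_zeros()
    return NeighborGraphs(knn=g.knn, snn=sp.csr_matrix(U), k=g.k,
                          construction="undirected_union",
                          include_self=g.include_self)


# ---------------------------------------------------------------------------
# Louvain


def _community_term(w_c: float, K_c: float, gamma: float, W: float,
                    variant: str) -> float:
    if variant == "local_moves_scaled":
        return (w_c - gamma * K_c ** 2 / (4.0 * W)) / W
    if variant == "all_moves_expected":
        return w_c - gamma * K_c ** 2 / (4.0 * W)
    raise ValueError(f"unknown variant {variant!r}")


def partition_quality(adj: sp.spmatrix, labels: np.ndarray, gamma: float,
                      variant: str) -> float:
    """Quality of a partition under one of the two documented scores.

    ``adj`` is a symmetric weighted adjacency (no self-loops expected at the
    cell level).
    """
    labels = np.asarray(labels)
    W = adj.sum() / 2.0  # symmetric: off-diagonal entries appear twice
    if W == 0:
        raise ValueError("graph has no edges")
    strengths = np.asarray(adj.sum(axis=1)).ravel()
    q = 0.0
    for c in np.unique(labels):
        members = labels == c
        w_c = adj[members][:, members].sum() / 2.0
        K_c = strengths[members].sum()
        q += _community_term(w_c, K_c, gamma, W, variant)
    return q


class _Level:
    """One aggregation level of the Louvain loop."""

    def __init__(self, adj: sp.csr_matrix, selfw: np.ndarray):
        self.n = adj.shape[0]
        self.adj = adj  # symmetric, zero diagonal
        self.selfw = selfw
        self.strength = np.asarray(adj.sum(axis=1)).ravel() + 2.0 * selfw
        self.neighbors = [
            (adj.indices[adj.indptr[u]: adj.indptr[u + 1]],
             adj.data[adj.indptr[u]: adj.indptr[u + 1]])
            for u in range(self.n)
        ]


def _move_phase(level: _Level, gamma: float, W: float, variant: str,
                rng: np.random.Generator, max_sweeps):
    n = level.n
    comm = np.arange(n)
    in_w = level.selfw.copy().astype(float)   # within-community weight
    tot_k = level.strength.copy().astype(float)
    size = np.ones(n, dtype=int)
    all_moves = variant == "all_moves_expected"

    order = rng.permutation(n)
    moved_any = False
    sweeps = 0
    quality_track = 0.0
    while True:
        moved_this_sweep = False
        for u in order:
            c0 = comm[u]
            nbrs, wts = level.neighbors[u]
            k_u = level.strength[u]
            # weight from u to each candidate community
            link = {}
            for v, w in zip(nbrs, wts):
                cv = comm[v]
                link[cv] = link.get(cv, 0.0) + w
            # detach u from its community
            size[c0] -= 1
            in_w[c0] -= link.get(c0, 0.0) + level.selfw[u]
            tot_k[c0] -= k_u

            if all_moves:
                candidates = list(np.flatnonzero(size > 0))
                if size[c0] == 0:
                    candidates.append(c0)  # its own (now empty) community
                else:
                    empty = np.flatnonzero(size == 0)
                    if empty.size:  # option to escape to an empty community
                        candidates.append(empty[0])
            else:
                candidates = sorted(set(link) | {c0})

            def gain(c):
                kc = link.get(c, 0.0)
                return (
                    _community_term(in_w[c] + kc + level.selfw[u],
                                    tot_k[c] + k_u, gamma, W, variant)
                    - _community_term(in_w[c], tot_k[c], gamma, W, variant)
                )

            base = gain(c0)
            best_c, best_gain = c0, base
            for c in candidates:
                if c == c0:
                    continue
                gc = gain(c)
                if gc > best_gain + 1e-12:
                    best_c, best_gain = c, gc
            # quality never decreases across accepted moves
            increment = best_gain - base
            assert increment >= 0.0
            quality_track += increment
            comm[u] = best_c
            size[best_c] += 1
            in_w[best_c] += link.get(best_c, 0.0) + level.selfw[u]
            tot_k[best_c] += k_u
            if best_c != c0:
                moved_this_sweep = True
                moved_any = True
        sweeps += 1
        if not moved_this_sweep:
            break
        if max_sweeps is not None and sweeps >= max_sweeps:
            break
    return comm, moved_any, sweeps


def _aggregate(level: _Level, comm: np.ndarray):
    ids, dense = np.unique(comm, return_inverse=True)
    m = ids.size
    coo = sp.coo_matrix(level.adj)
    r, c = dense[coo.row], dense[coo.col]
    cross = r != c
    adj = sp.csr_matrix(
        (coo.data[cross], (r[cross], c[cross])), shape=(m, m)
    )
    adj.sum_duplicates()
    selfw = np.zeros(m)
    inner = ~cross
    np.add.at(selfw, r[inner], coo.data[inner] / 2.0)
    np.add.at(selfw, dense, level.selfw)
    return _Level(adj, selfw), dense


def _louvain_component(adj: sp.csr_matrix, gamma: float, variant: str,
                       rng: np.random.Generator, max_iter, W: float):
    # W is the total weight of the WHOLE network: the null-model penalty is
    # global even when components are optimized independently
    n = adj.shape[0]
    if n == 1:
        return np.zeros(1, dtype=int), 0
    if adj.sum() == 0:
        return np.arange(n), 0
    level = _Level(adj, np.zeros(n))
    mapping = np.arange(n)
    total_sweeps = 0
    while True:
        comm, moved, sweeps = _move_phase(
            level, gamma, W, variant, rng,
            max_sweeps=max_iter if variant == "local_moves_scaled" else None,
        )
        total_sweeps += sweeps
        if not moved:
            break
        level, dense = _aggregate(level, comm)
        mapping = dense[mapping]  # original node -> aggregated node
        if level.n == 1:
            break
    _, labels = np.unique(mapping, return_inverse=True)
    return labels, total_sweeps


def louvain(g: NeighborGraphs, gamma: float = 1.0,
            variant: str = "local_moves_scaled", seed: int = 0,
            max_iter: int = 10) -> Clustering:
    """Louvain community detection on the SNN graph.

    ``variant`` selects the move-phase/quality-score pair documented in the
    module docstring.  Node scan order is a seeded shuffle; ties between
    equally good moves go to the first candidate in scan order.
    Disconnected components are clustered independently and label-offset.
    ``max_iter`` caps the sweeps per level for ``local_moves_scaled`` only.
    """
    if g.snn is None:
        raise ValueError("SNN graph required")
    adj = sp.csr_matrix(g.snn)
    n = adj.shape[0]
    if n == 0 or adj.nnz == 0:
        raise ValueError("empty graph")
    if variant not in ("local_moves_scaled", "all_moves_expected"):
        raise ValueError(f"unknown variant {variant!r}")
    rng = np.random.default_rng(seed)
    n_comp, comp = connected_components(adj, directed=False)
    W = adj.sum() / 2.0
    labels = np.zeros(n, dtype=int)
    offset = 0
    iterations = 0
    for ci in range(n_comp):
        members = np.flatnonzero(comp == ci)
        sub = adj[members][:, members]
        sub_labels, sweeps = _louvain_component(
            sub.tocsr(), gamma, variant, rng,
            max_iter if variant == "local_moves_scaled" else None, W,
        )
        labels[members] = sub_labels + offset
        offset += int(sub_labels.max()) + 1
        iterations = max(iterations, sweeps)
    quality = partition_quality(adj, labels, gamma, variant)
    return Clustering(
        labels=labels, resolution=gamma, quality=quality, variant=variant,
        seed=seed, n_iterations=iterations,
        provenance={"max_iter": max_iter, "n_components": int(n_comp)},
    )
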