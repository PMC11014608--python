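"""Per-stage similarity metrics and cluster alignment for paired runs.

Metrics cover every divergent pipeline stage: set overlap (Jaccard) for
cell/gene/HVG/marker sets, eigenvector angle (sine) and loading/scree
differences for PCA, per-cell neighborhood Jaccard and degree ratios for
SNN graphs, the adjusted Rand index for clusterings, Lin's concordance
correlation for log-fold changes, and the fraction of significance calls
that flip across p = 0.05.  The cluster-alignment routine orders one run's
clusters against the other's (for alluvial-style display) and matches
cluster colors by maximum-weight matching on overlap counts.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "ContingencyTable",
    "jaccard",
    "snn_concordance",
    "eig_sine",
    "pca_concordance",
    "ari",
    "ccc",
    "p_flip_fraction",
    "align_clusters",
    "embedding_knn_concordance",
    "contingency_from_labels",
]


@dataclass
class ContingencyTable:
    """Overlap counts between cluster i of run 1 and cluster j of run 2."""

    counts: np.ndarray          # clusters1 x clusters2
    clusters1: list
    clusters2: list

    @property
    def row_sizes(self):
        return self.counts.sum(axis=1)

    @property
    def col_sizes(self):
        return self.counts.sum(axis=0)


def contingency_from_labels(labels1, labels2) -> ContingencyTable:
    labels1, labels2 = np.asarray(labels1), np.asarray(labels2)
    if labels1.shape != labels2.shape:
        raise ValueError("label vectors differ in length")
    c1, i1 = np.unique(labels1, return_inverse=True)
    c2, i2 = np.unique(labels2, return_inverse=True)
    counts = np.zeros((c1.size, c2.size), dtype=int)
    np.add.at(counts, (i1, i2), 1)
    return ContingencyTable(counts=counts, clusters1=list(c1), clusters2=list(c2))


def jaccard(setA, setB) -> float:
    """|A & B| / |A | B|; both empty -> 1 (identical outputs score perfect)."""
    A, B = set(setA), set(setB)
    if not A and not B:
        return 1.0
    return len(A & B) / len(A | B)


def _neighbor_sets(snn: sp.spmatrix):
    snn = sp.csr_matrix(snn)
    out = []
    for i in range(snn.shape[0]):
        cols = snn.indices[snn.indptr[i]: snn.indptr[i + 1]]
        vals = snn.data[snn.indptr[i]: snn.indptr[i + 1]]
        out.append(set(cols[vals != 0]) - {i})
    return out


def snn_concordance(snn1, snn2):
    """Per-cell neighborhood Jaccard and log degree ratio between SNN graphs.

    Neighborhoods are the nonzero-weight neighbors excluding self.  Cells
    with degree 0 in both graphs score Jaccard 1 and ratio 0.  Returns
    ``(median_jaccard, median_abs_log_degree_ratio, per_cell)`` where
    ``per_cell`` has columns jaccard, log_degree_ratio.
    """
    if snn1.shape[0] != snn2.shape[0]:
        raise ValueError("SNN graphs cover different cell sets")
    sets1, sets2 = _neighbor_sets(snn1), _neighbor_sets(snn2)
    n = len(sets1)
    jac = np.empty(n)
    logratio = np.empty(n)
    for i in range(n):
        d1, d2 = len(sets1[i]), len(sets2[i])
        jac[i] = jaccard(sets1[i], sets2[i])
        if d1 == 0 and d2 == 0:
            logratio[i] = 0.0
        elif d1 == 0 or d2 == 0:
            logratio[i] = np.inf if d2 == 0 else -np.inf
        else:
            logratio[i] = np.log(d1 / d2)
    per_cell = np.column_stack([jac, logratio])
    finite = logratio[np.isfinite(logratio)]
    med_ratio = float(np.median(np.abs(finite))) if finite.size else float("inf")
    return float(np.median(jac)), med_ratio, per_cell


def eig_sine(v1, v2) -> float:
    """Sine of the angle between two vectors, sign-invariant.

    ``cos = |v1 . v2| / (||v1|| ||v2||)`` and ``sin = sqrt(1 - cos^2)``:
    0 for parallel vectors, 1 for orthogonal ones.
    """
    v1, v2 = np.asarray(v1, float), np.asarray(v2, float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("zero vector")
    cos = min(abs(float(v1 @ v2)) / (n1 * n2), 1.0)
    return float(np.sqrt(1.0 - cos ** 2))


def pca_concordance(p1, p2, shared_features: list = None):
    """Loading, scree and eigenvector-angle comparison of two PCA results.

    Returns ``(pc_loading_diff, scree_diff, sines)``:

    * ``pc_loading_diff`` — mean absolute difference of sign-aligned
      loadings over PCs 1-3, restricted to ``shared_features`` when the two
      runs selected different gene sets;
    * ``scree_diff`` — per-PC |difference in variance explained|;
    * ``sines`` — per-PC sine of the angle between the (shared-gene)
      eigenvectors.
    """
    K = min(p1.K, p2.K)
    if K < 3:
        raise ValueError("need at least 3 PCs in each run")
    L1, L2 = p1.loadings, p2.loadings
    if shared_features is not None:
        f1 = {f: i for i, f in enumerate(p1.features)}
        f2 = {f: i for i, f in enumerate(p2.features)}
        shared = [f for f in shared_features if f in f1 and f in f2]
        if not shared:
            raise ValueError("no shared genes between PCA results")
        L1 = L1[[f1[f] for f in shared]]
        L2 = L2[[f2[f] for f in shared]]
    elif L1.shape[0] != L2.shape[0]:
        raise ValueError("loadings differ in gene dimension; pass "
                         "shared_features")
    sines = [eig_sine(L1[:, k], L2[:, k]) for k in range(K)]
    diffs = []
    for k in range(min(3, K)):
        a, b = L1[:, k], L2[:, k]
        if float(a @ b) < 0:  # sign-align before differencing
            b = -b
        diffs.append(np.abs(a - b).mean())
    pc_loading_diff = float(np.mean(diffs))
    scree_diff = np.abs(
        np.asarray(p1.variance_explained[:K]) -
        np.asarray(p2.variance_explained[:K])
    ).tolist()
    return pc_loading_diff, scree_diff, sines


def ari(labels1, labels2) -> float:
    """Adjusted Rand index (standard permutation-model formula)."""
    labels1, labels2 = np.asarray(labels1), np.asarray(labels2)
    if labels1.shape != labels2.shape:
        raise ValueError("label vectors differ in length")
    return float(adjusted_rand_score(labels1, labels2))


def ccc(x, y, sample_moments: bool = False) -> float:
    """Lin's concordance correlation coefficient.

    ``rho_c = 2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2)``
    with population (1/n) moments by default (Lin's original convention);
    ``sample_moments`` switches to 1/(n-1).
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need equal-length vectors of length >= 2")
    ddof = 1 if sample_moments else 0
    vx, vy = x.var(ddof=ddof), y.var(ddof=ddof)
    if vx == 0 and vy == 0:
        raise ValueError("both vectors are constant")
    n = x.size
    cov = ((x - x.mean()) * (y - y.mean())).sum() / (n - ddof)
    return float(2 * cov / (vx + vy + (x.mean() - y.mean()) ** 2))


def p_flip_fraction(det1, det2, threshold: float = 0.05) -> float:
    """Fraction of shared (cluster, gene) keys whose significance call at
    ``threshold`` differs between the two DE tables."""
    t1 = det1.table.set_index(["cluster", "gene"])["p_adj"]
    t2 = det2.table.set_index(["cluster", "gene"])["p_adj"]
    shared = t1.index.intersection(t2.index)
    if shared.empty:
        raise ValueError("no shared (cluster, gene) keys")
    flips = (t1.loc[shared] < threshold) != (t2.loc[shared] < threshold)
    return float(flips.mean())


def align_clusters(ct: ContingencyTable):
    """Order run-2 clusters against run-1 and match colors.

    Run-1 clusters are ranked by decreasing size.  Each run-2 cluster is
    assigned the rank nearest its maximum-Jaccard run-1 partner; run-2
    clusters contending for the same partner are ordered by decreasing
    size, and exact Jaccard ties go to the lower-ranked run-1 cluster.
    Run-2 clusters with all-zero overlap are dropped with a warning.

    Returns ``(ordering, color_pairs)`` where ``ordering`` maps each kept
    run-2 cluster id to its display rank (0-based, a permutation), and
    ``color_pairs`` is the maximum-weight matching on overlap counts as
    (run-1 cluster, run-2 cluster) pairs.
    """
    counts = np.asarray(ct.counts, dtype=float)
    col_keep = counts.sum(axis=0) > 0
    if not col_keep.all():
        dropped = [c for c, k in zip(ct.clusters2, col_keep) if not k]
        warnings.warn(f"run-2 clusters with zero overlap dropped: {dropped}",
                      stacklevel=2)
    counts = counts[:, col_keep]
    clusters2 = [c for c, k in zip(ct.clusters2, col_keep) if k]

    row_sizes = counts.sum(axis=1)
    col_sizes = counts.sum(axis=0)
    # rank run-1 clusters by decreasing size (stable on index for ties)
    rank_of_row = np.empty(counts.shape[0], dtype=int)
    rank_of_row[np.lexsort((np.arange(counts.shape[0]), -row_sizes))] = (
        np.arange(counts.shape[0])
    )
    # best run-1 partner of each run-2 cluster by Jaccard; ties -> the
    # run-1 cluster with the lower rank
    desired_rank = np.empty(counts.shape[1], dtype=int)
    for j in range(counts.shape[1]):
        union = row_sizes + col_sizes[j] - counts[:, j]
        with np.errstate(invalid="ignore", divide="ignore"):
            jac = np.where(union > 0, counts[:, j] / union, 0.0)
        best = np.lexsort((rank_of_row, -jac))[0]
        desired_rank[j] = rank_of_row[best]
    # resolve conflicts: nearest rank to the partner, bigger cluster first
    order = np.lexsort((-col_sizes, desired_rank))
    ordering = {clusters2[j]: int(pos) for pos, j in enumerate(order)}

    full = np.asarray(ct.counts, dtype=float)
    ri, cj = linear_sum_assignment(full, maximize=True)
    color_pairs = [
        (ct.clusters1[i], ct.clusters2[j])
        for i, j in zip(ri, cj) if full[i, j] > 0
    ]
    return ordering, color_pairs


def embedding_knn_concordance(emb1, emb2, k: int = 20) -> float:
    """Median per-cell Jaccard of exact KNN neighborhoods (self excluded)
    between two 2-D embeddings of the same cells."""
    from .preprocess import PCAResult
    from .graph import knn_exact

    emb1, emb2 = np.asarray(emb1, float), np.asarray(emb2, float)
    if emb1.shape[0] != emb2.shape[0]:
        raise ValueError("embeddings cover different cell sets")
    n = emb1.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds {n} cells")
    jac = np.empty(n)
    g1 = knn_exact(_as_pca(emb1), k=k)
    g2 = knn_exact(_as_pca(emb2), k=k)
    for i in range(n):
        s1 = set(g1.knn[i]) - {i}
        s2 = set(g2.knn[i]) - {i}
        jac[i] = jaccard(s1, s2)
    return float(np.median(jac))


def _as_pca(emb):
    from .preprocess import PCAResult

    return PCAResult(embeddings=emb, loadings=np.eye(emb.shape[1]),
                     variance_explained=np.zeros(emb.shape[1]),
                     K=emb.shape[1])
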