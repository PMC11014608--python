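"""Filtering, normalization, HVG selection, scaling and PCA.

Every stage is parameterized so that either of the two documented behaviors
of the mainstream single-cell toolkits can be reproduced:

* HVG selection has two flavors: binned-dispersion z-scoring
  (:func:`hvg_binned_dispersion`, the classic mean/variance-plot approach)
  and loess variance-stabilizing selection (:func:`hvg_loess_vst`, which
  ranks genes by the variance of trend-standardized raw counts).
* Scaling optionally clips at an upper bound and optionally regresses out
  per-cell covariates (total counts, mitochondrial percentage) before
  standardizing.
* PCA is an exact truncated SVD with a deterministic sign convention so two
  runs can be compared without sign flips polluting the angle metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .io_formats import CountMatrix

__all__ = [
    "NormMatrix",
    "HVGResult",
    "PCAResult",
    "filter_cells_genes",
    "normalize_cp10k",
    "hvg_binned_dispersion",
    "hvg_loess_vst",
    "scale_and_regress",
    "pca_top_k",
    "loess_fit",
]


@dataclass
class NormMatrix:
    """Log-normalized expression Y_ig with per-cell size factors S_i.

    ``Y[i, g] = log_base(X[i, g] / S_i + 1)`` with
    ``S_i = (sum_g X[i, g]) / scale_factor``, so that for every cell
    ``sum_g (base**Y - 1) == scale_factor`` when all genes are retained.
    """

    Y: np.ndarray
    size_factor: np.ndarray
    barcodes: list
    features: list
    mito_mask: np.ndarray = None
    scale_factor: float = 10_000.0
    log_base: float = np.e
    provenance: dict = field(default_factory=dict)

    @property
    def n_cells(self):
        return self.Y.shape[0]

    @property
    def n_genes(self):
        return self.Y.shape[1]

    def expm1(self) -> np.ndarray:
        """Unlogged normalized expression ``base**Y - 1`` (= X/S)."""
        if self.log_base == np.e:
            return np.expm1(self.Y)
        return np.power(self.log_base, self.Y) - 1.0


@dataclass
class HVGResult:
    """Per-gene statistics and the selected highly variable gene set.

    Only the fields of the active flavor are populated: the binned flavor
    fills ``dispersion``/``bin_id``/``norm_dispersion``; the loess flavor
    fills ``predicted_variance``/``standardized_variance``.
    """

    flavor: str
    features: list
    mean: np.ndarray
    variance: np.ndarray
    selected: list
    dispersion: np.ndarray = None
    bin_id: np.ndarray = None
    norm_dispersion: np.ndarray = None
    predicted_variance: np.ndarray = None
    standardized_variance: np.ndarray = None
    params: dict = field(default_factory=dict)


@dataclass
class PCAResult:
    """Top-K principal components of the scaled matrix.

    ``variance_explained`` is each retained eigenvalue divided by the sum of
    *all* eigenvalues, so the entries are nonincreasing and sum to <= 1.
    Loadings columns are unit-norm with the largest-magnitude entry forced
    positive.
    """

    embeddings: np.ndarray
    loadings: np.ndarray
    variance_explained: np.ndarray
    K: int
    features: list = None
    barcodes: list = None


def filter_cells_genes(cm: CountMatrix, min_genes_per_cell: int = 200,
                       min_cells_per_gene: int = 3,
                       max_mito_pct: float = None,
                       min_umi: int = 0) -> CountMatrix:
    """Remove poor-quality cells, then minimally expressed genes.

    A cell is dropped when it has fewer than ``min_genes_per_cell`` detected
    genes, fewer than ``min_umi`` total counts, or a mitochondrial count
    percentage above ``max_mito_pct`` (skipped when ``None``).  Afterwards
    (single pass, cell filter first) genes detected in fewer than
    ``min_cells_per_gene`` remaining cells are dropped.
    """
    X = cm.counts
    detected = np.asarray((X > 0).sum(axis=1)).ravel()
    totals = np.asarray(X.sum(axis=1)).ravel()
    keep_cells = (detected >= min_genes_per_cell) & (totals >= min_umi)
    casualties = {
        "low_gene_cells": int((detected < min_genes_per_cell).sum()),
        "low_umi_cells": int((totals < min_umi).sum()),
        "high_mito_cells": 0,
    }
    if max_mito_pct is not None and cm.mito_mask.any():
        mito = np.asarray(X[:, cm.mito_mask].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(totals > 0, 100.0 * mito / totals, 0.0)
        casualties["high_mito_cells"] = int((pct > max_mito_pct).sum())
        keep_cells &= pct <= max_mito_pct
    if not keep_cells.any():
        raise ValueError(f"all cells removed by filtering: {casualties}")

    Xc = X[keep_cells]
    gene_cells = np.asarray((Xc > 0).sum(axis=0)).ravel()
    keep_genes = gene_cells >= min_cells_per_gene
    prov = dict(cm.provenance)
    prov["filter"] = {
        "min_genes_per_cell": min_genes_per_cell,
        "min_cells_per_gene": min_cells_per_gene,
        "max_mito_pct": max_mito_pct,
        "min_umi": min_umi,
        "cells_removed": int(cm.n_cells - keep_cells.sum()),
        "genes_removed": int(cm.n_genes - keep_genes.sum()),
        "casualties": casualties,
    }
    return CountMatrix(
        counts=Xc[:, keep_genes],
        barcodes=[b for b, k in zip(cm.barcodes, keep_cells) if k],
        features=[f for f, k in zip(cm.features, keep_genes) if k],
        mito_mask=cm.mito_mask[keep_genes],
        provenance=prov,
    )


def normalize_cp10k(cm: CountMatrix, scale_factor: float = 10_000.0,
                    log_base: float = np.e) -> NormMatrix:
    """Library-size normalization to ``scale_factor`` counts, then log1p."""
    totals = np.asarray(cm.counts.sum(axis=1), dtype=float).ravel()
    if np.any(totals == 0):
        raise ZeroDivisionError(
            f"{int((totals == 0).sum())} cells have zero total counts; "
            "filter before normalizing"
        )
    S = totals / scale_factor
    X = cm.counts.toarray().astype(float)
    Y = np.log1p(X / S[:, None])
    if log_base != np.e:
        Y /= np.log(log_base)
    return NormMatrix(
        Y=Y,
        size_factor=S,
        barcodes=list(cm.barcodes),
        features=list(cm.features),
        mito_mask=cm.mito_mask.copy(),
        scale_factor=scale_factor,
        log_base=log_base,
        provenance=dict(cm.provenance),
    )


def _top_n_indices(score: np.ndarray, eligible: np.ndarray, top_n: int):
    """Indices of the top_n scores among eligible genes; ties -> lower index."""
    idx = np.flatnonzero(eligible)
    if top_n > idx.size:
        raise ValueError(f"top_n={top_n} exceeds {idx.size} eligible genes")
    order = idx[np.lexsort((idx, -score[idx]))]
    return np.sort(order[:top_n])


def hvg_binned_dispersion(nm: NormMatrix, n_bins: int = 20, top_n: int = None,
                          mean_bounds: tuple = (0.0125, 3.0),
                          disp_bound: float = 0.5,
                          binning: str = "equal_width") -> HVGResult:
    """Binned-dispersion HVG selection (mean/variance-plot flavor).

    Per gene the dispersion ``d_g = var_g / mean_g`` is computed on the
    log-normalized matrix; genes are binned by mean expression and
    ``log(d_g)`` is z-scored within each bin.  Selection is either the
    ``top_n`` genes by normalized dispersion or, when ``top_n`` is None,
    thresholding: ``mean_bounds[0] <= mean < mean_bounds[1]`` and
    normalized dispersion ``>= disp_bound``.

    Zero-mean and zero-dispersion genes are excluded from z-scoring and can
    never be selected.  ``binning`` is ``equal_width`` (bins of equal span
    over the mean range) or ``equal_frequency`` (bins of equal gene count
    over ranked means).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    Y = nm.Y
    mu = Y.mean(axis=0)
    var = Y.var(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mu > 0, var / mu, 0.0)
    eligible = disp > 0

    bin_id = np.full(Y.shape[1], -1, dtype=int)
    if binning == "equal_width":
        lo, hi = mu[eligible].min(), mu[eligible].max()
        edges = np.linspace(lo, hi, n_bins + 1)
        bin_id[eligible] = np.clip(
            np.searchsorted(edges, mu[eligible], side="right") - 1, 0, n_bins - 1
        )
    elif binning == "equal_frequency":
        ranks = np.empty(eligible.sum(), dtype=int)
        ranks[np.argsort(mu[eligible], kind="stable")] = np.arange(eligible.sum())
        bin_id[eligible] = ranks * n_bins // eligible.sum()
    else:
        raise ValueError(f"unknown binning {binning!r}")

    logd = np.where(eligible, np.log(np.where(eligible, disp, 1.0)), 0.0)
    z = np.zeros_like(disp)
    for b in range(n_bins):
        members = bin_id == b
        if not members.any():
            continue
        vals = logd[members]
        center = vals.mean()
        # sd with the actual bin occupancy; a single-gene bin has no spread
        # information, so its gene keeps z = 0
        sd = vals.std(ddof=1) if vals.size > 1 else 0.0
        if sd > 0:
            z[members] = (vals - center) / sd

    if top_n is not None:
        sel_idx = _top_n_indices(z, eligible, top_n)
    else:
        ok = eligible & (mu >= mean_bounds[0]) & (mu < mean_bounds[1])
        ok &= z >= disp_bound
        sel_idx = np.flatnonzero(ok)
    return HVGResult(
        flavor="binned_dispersion",
        features=list(nm.features),
        mean=mu,
        variance=var,
        dispersion=disp,
        bin_id=bin_id,
        norm_dispersion=z,
        selected=[nm.features[i] for i in sel_idx],
        params={"n_bins": n_bins, "top_n": top_n, "mean_bounds": mean_bounds,
                "disp_bound": disp_bound, "binning": binning},
    )


def loess_fit(x: np.ndarray, y: np.ndarray, span: float = 0.3,
              degree: int = 2) -> np.ndarray:
    """Local polynomial regression evaluated at the data points.

    Classic loess: for each target point the nearest ``ceil(span * n)``
    points (by |x - x0|) are tricube-weighted and a degree-``degree``
    polynomial is fit by weighted least squares.  On collinear data the fit
    reproduces the line exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if np.unique(x).size < 2:
        raise ValueError("loess requires >= 2 distinct x values")
    q = max(degree + 1, int(np.ceil(span * n)))
    q = min(q, n)
    fitted = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argpartition(d, q - 1)[:q]
        h = d[idx].max()
        if h == 0:
            w = np.ones(q)
        else:
            w = np.clip(1 - (d[idx] / h) ** 3, 0, None) ** 3
            if w.sum() == 0:
                w = np.ones(q)
        xc = x[idx] - x[i]  # center for conditioning; predict at xc = 0
        V = np.vander(xc, degree + 1, increasing=True)
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(V * sw[:, None], y[idx] * sw, rcond=None)
        fitted[i] = beta[0]
    return fitted


def hvg_loess_vst(cm: CountMatrix, top_n: int = 2000, loess_span: float = 0.3,
                  clip: float = "sqrt_n") -> HVGResult:
    """Loess variance-stabilizing HVG selection on raw counts.

    A loess curve of ``log10(var_g)`` on ``log10(mean_g)`` gives each gene a
    predicted variance; counts are standardized with their own mean and the
    predicted standard deviation, clipped above at ``clip`` (default
    ``sqrt(n_cells)``), and genes are ranked by the variance of the clipped
    standardized values, ``sum_i z_ig^2 / (n_cells - 1)``.
    """
    X = cm.counts.toarray().astype(float)
    n_cells, n_genes = X.shape
    if top_n > n_genes:
        raise ValueError(f"top_n={top_n} exceeds {n_genes} genes")
    mu = X.mean(axis=0)
    var = X.var(axis=0, ddof=1)
    fit_mask = (var > 0) & (mu > 0)
    if not fit_mask.any():
        raise ValueError("all genes have zero variance")
    if clip == "sqrt_n":
        clip = np.sqrt(n_cells)

    pred_var = np.zeros(n_genes)
    fitted = loess_fit(np.log10(mu[fit_mask]), np.log10(var[fit_mask]),
                       span=loess_span, degree=2)
    pred_var[fit_mask] = 10.0 ** fitted

    std_var = np.zeros(n_genes)
    sd = np.sqrt(pred_var[fit_mask])
    Z = (X[:, fit_mask] - mu[fit_mask]) / sd
    if clip is not None and np.isfinite(clip):
        Z = np.minimum(Z, clip)
    std_var[fit_mask] = (Z ** 2).sum(axis=0) / (n_cells - 1)

    sel_idx = _top_n_indices(std_var, fit_mask, top_n)
    return HVGResult(
        flavor="loess_vst",
        features=list(cm.features),
        mean=mu,
        variance=var,
        predicted_variance=pred_var,
        standardized_variance=std_var,
        selected=[cm.features[i] for i in sel_idx],
        params={"top_n": top_n, "loess_span": loess_span,
                "clip": None if clip is None else float(clip)},
    )


def scale_and_regress(nm: NormMatrix, genes: list = None, clip_max: float = None,
                      covariates: np.ndarray = None,
                      symmetric_clip: bool = False):
    """Per-gene standardization with optional covariate regression and clip.

    When ``covariates`` (cells x c) is given, each gene's vector is first
    replaced by its OLS residuals on the covariates (with intercept).  Genes
    are then centered to mean 0 and scaled to unit variance; values above
    ``clip_max`` are clipped (and below ``-clip_max`` too when
    ``symmetric_clip``).  Zero-variance genes become all-zero columns and
    are reported in the returned flags.

    Returns ``(scaled cells x genes array, gene list, zero_variance flags)``.
    """
    if genes is None:
        genes = list(nm.features)
    col = {f: j for j, f in enumerate(nm.features)}
    missing = [g for g in genes if g not in col]
    if missing:
        raise KeyError(f"genes not in matrix: {missing[:5]}")
    M = nm.Y[:, [col[g] for g in genes]].astype(float).copy()

    if covariates is not None:
        C = np.column_stack([np.ones(nm.n_cells), np.asarray(covariates, float)])
        beta, *_ = np.linalg.lstsq(C, M, rcond=None)
        M = M - C @ beta

    M -= M.mean(axis=0)
    sd = M.std(axis=0)
    zero_var = sd <= 1e-12
    sd_safe = np.where(zero_var, 1.0, sd)
    M /= sd_safe
    M[:, zero_var] = 0.0
    if clip_max is not None:
        M = np.minimum(M, clip_max)
        if symmetric_clip:
            M = np.maximum(M, -clip_max)
    return M, list(genes), zero_var


def pca_top_k(scaled: np.ndarray, K: int = 50, seed: int = 0,
              features: list = None, barcodes: list = None) -> PCAResult:
    """Exact truncated SVD of the column-centered matrix.

    ``seed`` is accepted for interface symmetry with stochastic stages; the
    decomposition is deterministic.  If ``K`` exceeds the matrix rank the
    returned components are truncated to the rank with a warning.
    """
    X = np.asarray(scaled, dtype=float)
    n, p = X.shape
    if K > min(n - 1, p):
        raise ValueError(f"K={K} exceeds min(n_cells - 1, n_genes) = "
                         f"{min(n - 1, p)}")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = s ** 2 / (n - 1)
    total = eigvals.sum()
    rank = int((s > s[0] * max(n, p) * np.finfo(float).eps).sum()) if s.size else 0
    if K > rank:
        warnings.warn(f"K={K} exceeds rank {rank}; truncating", stacklevel=2)
        K = rank
    U, s, Vt = U[:, :K], s[:K], Vt[:K]
    # deterministic sign: largest-|loading| entry of each PC is positive
    for k in range(K):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    return PCAResult(
        embeddings=U * s,
        loadings=Vt.T,
        variance_explained=eigvals[:K] / total if total > 0 else eigvals[:K],
        K=K,
        features=features,
        barcodes=barcodes,
    )
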