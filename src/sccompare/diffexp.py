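"""One-vs-rest Wilcoxon rank-sum DE with the divergent toolkit conventions.

Each divergence source is an independent toggle:

* tie correction in the rank-sum variance (on for the Seurat-style presets,
  off for the Scanpy-style default),
* four log-fold-change formulas differing only in where the pseudocount
  enters (see :func:`logfc`),
* Bonferroni vs Benjamini-Hochberg p adjustment,
* marker filtering by expression fraction, |logFC| and adjusted p.

With ``m1``/``m2`` the arithmetic means of the unlogged normalized
expression ``expm1(Y)`` over the cluster (n1 cells) and the rest (n2
cells):

=============  ==========================================================
reference      log2((m1 + eps) / (m2 + eps))
seurat_v5      log2(m1 + 1/n1) - log2(m2 + 1/n2)   (pseudocount 1/n)
seurat_v4      log2(m1 + 1) - log2(m2 + 1)          (pseudocount 1)
scanpy         log2(expm1(mean of Y) + eps) per group, i.e. a geometric-
               mean-based value with pseudocount eps = 1e-9
=============  ==========================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import NormMatrix

__all__ = [
    "DETable",
    "wilcoxon_one_vs_rest",
    "logfc",
    "adjust_p",
    "marker_filter",
    "run_de",
    "DE_PRESETS",
]


@dataclass
class DETable:
    """Per-(cluster, gene) DE results.

    ``table`` is a DataFrame with columns cluster, gene, logfc, z, p, p_adj,
    pct_in, pct_out, passed_filter.
    """

    table: pd.DataFrame
    formula: str
    adjust: str
    tie_correct: bool
    filter_params: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def significant_genes(self, threshold: float = 0.05) -> set:
        """Union over clusters of genes with adjusted p below ``threshold``."""
        t = self.table
        return set(t.loc[t["p_adj"] < threshold, "gene"])

    def marker_keys(self) -> set:
        """(cluster, gene) pairs that passed the active filter."""
        t = self.table
        return set(map(tuple, t.loc[t["passed_filter"], ["cluster", "gene"]]
                       .itertuples(index=False)))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _rank_sum_stats(Y: np.ndarray, in_group: np.ndarray, tie_correct: bool):
    """Vectorized one-group-vs-rest rank-sum z over all genes (columns)."""
    N, n1 = Y.shape[0], int(in_group.sum())
    n2 = N - n1
    ranks = stats.rankdata(Y, axis=0, method="average")
    W = ranks[in_group].sum(axis=0)
    mu_W = n1 * (N + 1) / 2.0
    var_W = np.full(Y.shape[1], n1 * n2 * (N + 1) / 12.0)
    if tie_correct:
        for g in range(Y.shape[1]):
            _, counts = np.unique(Y[:, g], return_counts=True)
            t = counts[counts > 1]
            if t.size:
                var_W[g] = (
                    n1 * n2 / 12.0
                    * ((N + 1) - (t ** 3 - t).sum() / (N * (N - 1)))
                )
    sd = np.sqrt(np.maximum(var_W, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (W - mu_W) / sd, 0.0)
    p = np.where(sd > 0, 2.0 * stats.norm.sf(np.abs(z)), 1.0)
    return z, np.minimum(p, 1.0)


def wilcoxon_one_vs_rest(nm: NormMatrix, labels, tie_correct: bool) -> pd.DataFrame:
    """Wilcoxon rank-sum z and two-sided normal-approximation p per gene.

    Each cluster is compared against all other cells.  The variance of the
    rank sum includes the tie-correction term iff ``tie_correct``; a gene
    with zero rank variance (all values identical) gets p = 1.
    """
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise ValueError("need at least two clusters")
    rows = []
    for c in clusters:
        in_group = labels == c
        if in_group.sum() == 0 or (~in_group).sum() == 0:
            raise ValueError(f"cluster {c} leaves an empty group")
        z, p = _rank_sum_stats(nm.Y, in_group, tie_correct)
        rows.append(pd.DataFrame({
            "cluster": c, "gene": nm.features, "z": z, "p": p,
        }))
    return pd.concat(rows, ignore_index=True)


def logfc(nm: NormMatrix, cluster_cells: np.ndarray, rest_cells: np.ndarray,
          formula: str = "reference", base: float = 2.0,
          eps: float = 1e-9) -> np.ndarray:
    """Per-gene log-fold change between two cell groups under one formula."""
    cluster_cells = np.asarray(cluster_cells)
    rest_cells = np.asarray(rest_cells)
    n1, n2 = cluster_cells.size, rest_cells.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    E = nm.expm1()
    m1 = E[cluster_cells].mean(axis=0)
    m2 = E[rest_cells].mean(axis=0)
    log = lambda v: np.log(v) / np.log(base)  # noqa: E731
    if formula == "reference":
        return log(m1 + eps) - log(m2 + eps)
    if formula == "seurat_v5":
        return log(m1 + 1.0 / n1) - log(m2 + 1.0 / n2)
    if formula == "seurat_v4":
        return log(m1 + 1.0) - log(m2 + 1.0)
    if formula == "scanpy":
        # mean is taken in log space, so this is a geometric-mean-based value
        ln_scale = np.log(nm.log_base)  # rescale Y to natural-log units
        g1 = np.expm1(nm.Y[cluster_cells].mean(axis=0) * ln_scale)
        g2 = np.expm1(nm.Y[rest_cells].mean(axis=0) * ln_scale)
        return log(g1 + eps) - log(g2 + eps)
    raise ValueError(f"unknown formula {formula!r}")


def adjust_p(p_values, method: str, m: int = None) -> np.ndarray:
    """Bonferroni or Benjamini-Hochberg adjustment over ``m`` tests.

    ``m`` defaults to ``len(p_values)`` and may exceed it (genes tested but
    dropped upstream still count toward the family).
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be >= number of p-values")
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method == "bh":
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / np.arange(1, p.size + 1)
        # step-up: running minimum from the largest p downwards
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(p)
        out[order] = np.minimum(ranked, 1.0)
        return out
    raise ValueError(f"unknown method {method!r}")


def marker_filter(det: DETable, min_pct: float = 0.0,
                  logfc_threshold: float = 0.0, p_threshold: float = 1.01,
                  only_pos: bool = False) -> DETable:
    """Flag rows passing the marker filter; returns a new DETable.

    A row passes iff ``max(pct_in, pct_out) >= min_pct``, ``|logfc| >=
    logfc_threshold`` (the signed value when ``only_pos``), and
    ``p_adj < p_threshold``.  With all thresholds disabled every row passes
    (the no-filtering default behavior).
    """
    t = det.table.copy()
    pct_ok = np.maximum(t["pct_in"], t["pct_out"]) >= min_pct
    lfc = t["logfc"] if only_pos else t["logfc"].abs()
    lfc_ok = lfc >= logfc_threshold
    p_ok = t["p_adj"] < p_threshold
    t["passed_filter"] = pct_ok & lfc_ok & p_ok
    return DETable(
        table=t, formula=det.formula, adjust=det.adjust,
        tie_correct=det.tie_correct,
        filter_params={"min_pct": min_pct, "logfc_threshold": logfc_threshold,
                       "p_threshold": p_threshold, "only_pos": only_pos},
        provenance=det.provenance,
    )


#: Composite per-toolkit DE behaviors.  ``scanpy_filtered`` applies the
#: separate filtering step's defaults on top of the Scanpy-style test.
DE_PRESETS = {
    "seurat_v5": {
        "tie_correct": True, "formula": "seurat_v5", "adjust": "bonferroni",
        "filter": {"min_pct": 0.01, "logfc_threshold": 0.1,
                   "p_threshold": 0.05, "only_pos": False},
    },
    "seurat_v4": {
        "tie_correct": True, "formula": "seurat_v4", "adjust": "bonferroni",
        "filter": {"min_pct": 0.1, "logfc_threshold": 0.25,
                   "p_threshold": 0.05, "only_pos": False},
    },
    "scanpy_default": {
        "tie_correct": False, "formula": "scanpy", "adjust": "bh",
        "filter": None,
    },
    "scanpy_filtered": {
        "tie_correct": False, "formula": "scanpy", "adjust": "bh",
        "filter": {"min_pct": 0.25, "logfc_threshold": 1.0,
                   "p_threshold": 1.01, "only_pos": False},
    },
}


def run_de(nm: NormMatrix, labels, preset: str = None, *,
           tie_correct: bool = None, formula: str = None, adjust: str = None,
           filter_params: dict = None) -> DETable:
    """One-vs-rest DE for every cluster under a preset or explicit toggles.

    ``preset`` is a key of :data:`DE_PRESETS`; individual keyword toggles
    override the preset so divergence sources can be flipped independently.
    """
    cfg = dict(DE_PRESETS[preset]) if preset else {
        "tie_correct": True, "formula": "reference", "adjust": "bonferroni",
        "filter": None,
    }
    if tie_correct is not None:
        cfg["tie_correct"] = tie_correct
    if formula is not None:
        cfg["formula"] = formula
    if adjust is not None:
        cfg["adjust"] = adjust
    if filter_params is not None:
        cfg["filter"] = filter_params

    labels = np.asarray(labels)
    stats_df = wilcoxon_one_vs_rest(nm, labels, cfg["tie_correct"])
    X_pos = nm.Y > 0  # detection: nonzero count iff nonzero normalized value
    parts = []
    for c, sub in stats_df.groupby("cluster", sort=True):
        in_idx = np.flatnonzero(labels == c)
        out_idx = np.flatnonzero(labels != c)
        lfc = logfc(nm, in_idx, out_idx, formula=cfg["formula"])
        sub = sub.copy()
        sub["logfc"] = lfc
        sub["p_adj"] = adjust_p(sub["p"].to_numpy(), cfg["adjust"],
                                m=len(nm.features))
        sub["pct_in"] = X_pos[in_idx].mean(axis=0)
        sub["pct_out"] = X_pos[out_idx].mean(axis=0)
        parts.append(sub)
    table = pd.concat(parts, ignore_index=True)
    table["passed_filter"] = True
    det = DETable(
        table=table[["cluster", "gene", "logfc", "z", "p", "p_adj",
                     "pct_in", "pct_out", "passed_filter"]],
        formula=cfg["formula"], adjust=cfg["adjust"],
        tie_correct=cfg["tie_correct"],
        provenance={"preset": preset, "m_per_cluster": len(nm.features),
                    **{k: v for k, v in cfg.items() if k != "filter"}},
    )
    if cfg["filter"]:
        det = marker_filter(det, **cfg["filter"])
    return det
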