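"""Paired pipeline runs, downsampling sweeps, and seed-sensitivity studies.

:func:`run_pipeline` executes the full workflow (filter -> normalize ->
HVG -> scale -> PCA -> KNN -> SNN -> Louvain -> DE) under one of two
presets that mirror the documented default behaviors of the mainstream
toolkits, or under a custom preset dict with any divergence source toggled
independently:

* ``seurat_like`` — loess-VST HVGs, clip-10 scaling without regression,
  Jaccard-pruned SNN, local-move Louvain at resolution 1.0, tie-corrected
  Wilcoxon with Bonferroni and marker filtering.
* ``scanpy_like`` — binned-dispersion HVGs, regression on total counts and
  mitochondrial fraction without clipping, undirected-union SNN, all-move
  Louvain at resolution 0.8, uncorrected-tie Wilcoxon with BH and no
  filtering.

:func:`compare_runs` reduces a pair of runs to the fixed per-stage metric
vocabulary; :func:`downsample_sweep` applies the 5% sufficiency rule
against a reference variability (by default the seurat_like vs scanpy_like
comparison at full size); :func:`seed_sensitivity` reruns a stochastic
stage across seeds on frozen upstream input.
"""

from __future__ import annotations

import copy
import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import concordance as cc
from . import diffexp, graph, preprocess
from .io_formats import ConcordanceReport, CountMatrix
from .synthetic import downsample_cells, downsample_reads

__all__ = [
    "RunArtifacts",
    "SweepResult",
    "PIPELINE_PRESETS",
    "make_preset",
    "run_pipeline",
    "compare_runs",
    "downsample_sweep",
    "seed_sensitivity",
    "SIMILARITY_METRICS",
    "DISSIMILARITY_METRICS",
]

STAGES = ("filter", "norm", "hvg", "scale", "pca", "knn", "snn", "cluster",
          "embedding", "de")

PIPELINE_PRESETS = {
    "seurat_like": {
        "filter": {"min_genes_per_cell": 200, "min_cells_per_gene": 3,
                   "max_mito_pct": 20.0, "min_umi": 0},
        "norm": {"scale_factor": 10_000.0},
        "hvg": {"flavor": "loess_vst", "top_n": 2000, "loess_span": 0.3},
        "scale": {"clip_max": 10.0, "regress": False},
        "pca": {"K": 50},
        "knn": {"k": 20},
        "snn": {"construction": "jaccard_prune", "prune": 1 / 15},
        "cluster": {"variant": "local_moves_scaled", "gamma": 1.0,
                    "max_iter": 10},
        "de": {"preset": "seurat_v5"},
    },
    "scanpy_like": {
        "filter": {"min_genes_per_cell": 200, "min_cells_per_gene": 3,
                   "max_mito_pct": 20.0, "min_umi": 0},
        "norm": {"scale_factor": 10_000.0},
        "hvg": {"flavor": "binned_dispersion", "n_bins": 20, "top_n": None,
                "mean_bounds": (0.0125, 3.0), "disp_bound": 0.5},
        "scale": {"clip_max": None, "regress": True},
        "pca": {"K": 50},
        "knn": {"k": 20},
        "snn": {"construction": "undirected_union"},
        "cluster": {"variant": "all_moves_expected", "gamma": 0.8,
                    "max_iter": None},
        "de": {"preset": "scanpy_default"},
    },
}

#: metrics where larger is better / where smaller is better
SIMILARITY_METRICS = frozenset({
    "jaccard_cells", "jaccard_genes", "jaccard_hvg", "snn_median_jaccard",
    "ari", "embedding_knn_median_jaccard", "jaccard_sig_markers",
    "jaccard_markers", "ccc_logfc",
})
DISSIMILARITY_METRICS = frozenset({
    "pc_loading_diff", "snn_median_log_degree_ratio", "p_flip_fraction",
})


def make_preset(name: str, overrides: dict = None) -> dict:
    """Deep copy of a named preset with optional per-stage overrides."""
    preset = copy.deepcopy(PIPELINE_PRESETS[name])
    for stage, vals in (overrides or {}).items():
        preset.setdefault(stage, {}).update(vals)
    return preset


@dataclass
class RunArtifacts:
    """Every intermediate output of one pipeline run, keyed by stage."""

    stages: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __getitem__(self, key):
        if key not in STAGES:
            raise KeyError(f"unknown stage {key!r}")
        return self.stages.get(key)

    def has(self, key) -> bool:
        return self.stages.get(key) is not None

    def save(self, dir_path) -> None:
        """Serialize the comparable artifacts of this run to a directory."""
        os.makedirs(dir_path, exist_ok=True)
        j = os.path.join
        manifest = {"provenance": self.provenance, "stages": {}}
        if self.has("filter"):
            cells, genes = self.stages["filter"]
            with open(j(dir_path, "cells.txt"), "w") as fh:
                fh.writelines(c + "\n" for c in cells)
            with open(j(dir_path, "genes.txt"), "w") as fh:
                fh.writelines(g + "\n" for g in genes)
            manifest["stages"]["filter"] = ["cells.txt", "genes.txt"]
        if self.has("hvg"):
            with open(j(dir_path, "hvg.txt"), "w") as fh:
                fh.writelines(g + "\n" for g in self.stages["hvg"].selected)
            manifest["stages"]["hvg"] = "hvg.txt"
        if self.has("pca"):
            p = self.stages["pca"]
            cols = [f"PC{i + 1}" for i in range(p.K)]
            pd.DataFrame(p.embeddings, columns=cols).to_csv(
                j(dir_path, "pca_embeddings.csv"), index=False)
            load = pd.DataFrame(p.loadings, columns=cols)
            if p.features is not None:
                load.insert(0, "gene", p.features)
            load.to_csv(j(dir_path, "pca_loadings.csv"), index=False)
            pd.DataFrame({"PC": cols,
                          "variance_explained": p.variance_explained}
                         ).to_csv(j(dir_path, "pca_variance.csv"), index=False)
            manifest["stages"]["pca"] = ["pca_embeddings.csv",
                                         "pca_loadings.csv",
                                         "pca_variance.csv"]
        if self.has("snn"):
            coo = sp.coo_matrix(self.stages["snn"].snn)
            keep = coo.row < coo.col
            pd.DataFrame({"i": coo.row[keep], "j": coo.col[keep],
                          "weight": coo.data[keep]}).to_csv(
                j(dir_path, "snn_edges.csv"), index=False)
            manifest["stages"]["snn"] = "snn_edges.csv"
        if self.has("cluster"):
            cells = self.stages["filter"][0] if self.has("filter") else [
                str(i) for i in range(len(self.stages["cluster"].labels))]
            pd.DataFrame({"barcode": cells,
                          "label": self.stages["cluster"].labels}).to_csv(
                j(dir_path, "labels.csv"), index=False)
            manifest["stages"]["cluster"] = "labels.csv"
        if self.has("embedding"):
            pd.DataFrame(self.stages["embedding"],
                         columns=["dim1", "dim2"]).to_csv(
                j(dir_path, "embedding.csv"), index=False)
            manifest["stages"]["embedding"] = "embedding.csv"
        if self.has("de"):
            self.stages["de"].to_csv(j(dir_path, "de.csv"))
            manifest["stages"]["de"] = "de.csv"
        with open(j(dir_path, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
            fh.write("\n")


def run_pipeline(cm: CountMatrix, preset="seurat_like", seed: int = 0,
                 overrides: dict = None, labels_override=None,
                 embedding_override=None) -> RunArtifacts:
    """Execute the full pipeline under a preset; returns all intermediates.

    ``preset`` is a preset name or a full preset dict; ``overrides`` patches
    individual stage parameters.  ``labels_override`` substitutes externally
    supplied cluster labels before DE (used when transferring full-size
    labels onto downsampled cells); ``embedding_override`` substitutes an
    externally computed 2-D embedding (e.g. UMAP) for the default PC1-2
    embedding.  Deterministic given ``seed``.
    """
    cfg = (make_preset(preset, overrides) if isinstance(preset, str)
           else copy.deepcopy(preset))
    if not isinstance(preset, str) and overrides:
        for stage, vals in overrides.items():
            cfg.setdefault(stage, {}).update(vals)
    art = RunArtifacts(provenance={
        "preset": preset if isinstance(preset, str) else "custom",
        "seed": seed, "config": _jsonable(cfg),
    })
    try:
        fcm = preprocess.filter_cells_genes(cm, **cfg["filter"])
        art.stages["filter"] = (list(fcm.barcodes), list(fcm.features))

        nm = preprocess.normalize_cp10k(fcm, **cfg["norm"])
        art.stages["norm"] = nm

        hvg_cfg = dict(cfg["hvg"])
        flavor = hvg_cfg.pop("flavor")
        if flavor == "loess_vst":
            hvg_cfg["top_n"] = min(hvg_cfg.get("top_n", 2000), fcm.n_genes)
            hvg = preprocess.hvg_loess_vst(fcm, **hvg_cfg)
        elif flavor == "binned_dispersion":
            hvg = preprocess.hvg_binned_dispersion(nm, **hvg_cfg)
        else:
            raise ValueError(f"unknown HVG flavor {flavor!r}")
        if len(hvg.selected) < 3:
            raise ValueError("fewer than 3 HVGs selected")
        art.stages["hvg"] = hvg

        scale_cfg = dict(cfg["scale"])
        covariates = None
        if scale_cfg.pop("regress", False):
            totals = np.asarray(fcm.counts.sum(axis=1), float).ravel()
            mito = np.asarray(fcm.counts[:, fcm.mito_mask].sum(axis=1),
                              float).ravel() if fcm.mito_mask.any() else (
                np.zeros(fcm.n_cells))
            covariates = np.column_stack([totals, 100.0 * mito / totals])
        scaled, genes, zero_var = preprocess.scale_and_regress(
            nm, genes=hvg.selected, covariates=covariates, **scale_cfg)
        art.stages["scale"] = (scaled, genes)

        K = min(cfg["pca"]["K"], len(genes), scaled.shape[0] - 1)
        pca = preprocess.pca_top_k(scaled, K=K, seed=seed, features=genes,
                                   barcodes=fcm.barcodes)
        art.stages["pca"] = pca

        g = graph.knn_exact(pca, k=min(cfg["knn"]["k"], fcm.n_cells))
        art.stages["knn"] = g
        snn_cfg = dict(cfg["snn"])
        if snn_cfg.pop("construction") == "jaccard_prune":
            g = graph.snn_jaccard_prune(g, **snn_cfg)
        else:
            g = graph.snn_undirected_union(g)
        art.stages["snn"] = g

        clus = graph.louvain(
            g, gamma=cfg["cluster"]["gamma"],
            variant=cfg["cluster"]["variant"], seed=seed,
            max_iter=cfg["cluster"].get("max_iter") or 10,
        )
        art.stages["cluster"] = clus

        art.stages["embedding"] = (
            np.asarray(embedding_override, float)
            if embedding_override is not None
            else pca.embeddings[:, :2].copy()
        )

        de_labels = (np.asarray(labels_override) if labels_override is not None
                     else clus.labels)
        art.provenance["de_labels"] = (
            "override" if labels_override is not None else "cluster")
        art.stages["de"] = diffexp.run_de(nm, de_labels, **cfg["de"])
    except Exception as exc:
        done = [s for s in STAGES if s in art.stages]
        failed = next((s for s in STAGES if s not in art.stages), "de")
        raise RuntimeError(
            f"pipeline failed at stage {failed!r} "
            f"(completed: {done}): {exc}"
        ) from exc
    return art


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _shared_cell_index(a: RunArtifacts, b: RunArtifacts):
    cells_a, cells_b = a["filter"][0], b["filter"][0]
    shared = [c for c in cells_a if c in set(cells_b)]
    if not shared:
        raise ValueError("runs have disjoint cell universes")
    if len(shared) < len(cells_a) or len(shared) < len(cells_b):
        warnings.warn("cell universes differ; intersecting", stacklevel=3)
    pos_a = {c: i for i, c in enumerate(cells_a)}
    pos_b = {c: i for i, c in enumerate(cells_b)}
    ia = np.array([pos_a[c] for c in shared])
    ib = np.array([pos_b[c] for c in shared])
    return ia, ib


def compare_runs(a: RunArtifacts, b: RunArtifacts) -> ConcordanceReport:
    """Reduce two runs to the fixed per-stage concordance metric vocabulary.

    Metrics whose input stage is missing in either run are reported as
    ``None``.  Graph, cluster and embedding metrics are computed on the
    intersected cell universe; DE metrics are computed on shared
    (cluster, gene) keys after mapping run-b cluster ids onto run-a ids by
    maximum-weight matching of the cluster overlap counts.
    """
    metrics = {name: None for name in
               ("jaccard_cells", "jaccard_genes", "jaccard_hvg",
                "pc_loading_diff", "eig_sine", "scree_diff",
                "snn_median_jaccard", "snn_median_log_degree_ratio", "ari",
                "embedding_knn_median_jaccard", "jaccard_sig_markers",
                "jaccard_markers", "ccc_logfc", "p_flip_fraction")}
    prov = {"run_a": a.provenance.get("preset"),
            "run_b": b.provenance.get("preset"), "aligned": {}}

    if a.has("filter") and b.has("filter"):
        metrics["jaccard_cells"] = cc.jaccard(a["filter"][0], b["filter"][0])
        metrics["jaccard_genes"] = cc.jaccard(a["filter"][1], b["filter"][1])
    if a.has("hvg") and b.has("hvg"):
        metrics["jaccard_hvg"] = cc.jaccard(a["hvg"].selected,
                                            b["hvg"].selected)
    if a.has("pca") and b.has("pca"):
        try:
            shared = sorted(set(a["pca"].features) & set(b["pca"].features))
            diff, scree, sines = cc.pca_concordance(
                a["pca"], b["pca"], shared_features=shared)
            metrics["pc_loading_diff"] = diff
            metrics["scree_diff"] = scree
            metrics["eig_sine"] = sines
        except ValueError as exc:
            warnings.warn(f"PCA metrics unavailable: {exc}", stacklevel=2)

    ia = ib = None
    if a.has("filter") and b.has("filter"):
        ia, ib = _shared_cell_index(a, b)
    if ia is not None and a.has("snn") and b.has("snn"):
        s1 = a["snn"].snn[ia][:, ia]
        s2 = b["snn"].snn[ib][:, ib]
        med_j, med_r, _ = cc.snn_concordance(s1, s2)
        metrics["snn_median_jaccard"] = med_j
        metrics["snn_median_log_degree_ratio"] = (
            med_r if np.isfinite(med_r) else None)
    la = lb = None
    if ia is not None and a.has("cluster") and b.has("cluster"):
        la = np.asarray(a["cluster"].labels)[ia]
        lb = np.asarray(b["cluster"].labels)[ib]
        metrics["ari"] = cc.ari(la, lb)
    if ia is not None and a.has("embedding") and b.has("embedding"):
        e1 = np.asarray(a["embedding"])[ia]
        e2 = np.asarray(b["embedding"])[ib]
        metrics["embedding_knn_median_jaccard"] = cc.embedding_knn_concordance(
            e1, e2, k=min(20, len(ia)))

    if a.has("de") and b.has("de"):
        det_a, det_b = a["de"], b["de"]
        metrics["jaccard_sig_markers"] = cc.jaccard(
            det_a.significant_genes(), det_b.significant_genes())
        # map run-b cluster ids onto run-a ids before keying on
        # (cluster, gene); identity when the labelings already agree
        tb = det_b.table
        if la is not None and not np.array_equal(la, lb):
            ct = cc.contingency_from_labels(la, lb)
            _, pairs = cc.align_clusters(ct)
            mapping = {b_id: a_id for a_id, b_id in pairs}
            tb = tb.copy()
            # unmatched run-b clusters get fresh ids so keys cannot collide
            tb["cluster"] = tb["cluster"].map(
                lambda c: mapping.get(c, f"unmatched_{c}"))
            prov["aligned"]["de_clusters"] = {str(k): _jsonable(v) for k, v
                                              in mapping.items()}
        det_b_m = diffexp.DETable(table=tb, formula=det_b.formula,
                                  adjust=det_b.adjust,
                                  tie_correct=det_b.tie_correct)
        metrics["jaccard_markers"] = cc.jaccard(det_a.marker_keys(),
                                                det_b_m.marker_keys())
        k_a = det_a.table.set_index(["cluster", "gene"])["logfc"]
        k_b = det_b_m.table.set_index(["cluster", "gene"])["logfc"]
        shared = k_a.index.intersection(k_b.index)
        if len(shared) >= 2:
            try:
                metrics["ccc_logfc"] = cc.ccc(k_a.loc[shared].to_numpy(),
                                              k_b.loc[shared].to_numpy())
            except ValueError:
                metrics["ccc_logfc"] = 1.0  # identical constant vectors
            metrics["p_flip_fraction"] = cc.p_flip_fraction(det_a, det_b_m)
    return ConcordanceReport(metrics=_jsonable(metrics), provenance=prov)


@dataclass
class SweepResult:
    """Downsampling sweep outcome under the 5% sufficiency rule."""

    axis: str
    fractions: list
    per_fraction: dict          # fraction -> {metric: value}
    v_ref: dict                 # metric -> reference variability value
    sufficiency: dict           # metric -> smallest sufficient fraction/None
    failed_fractions: list = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "axis": self.axis, "fractions": self.fractions,
            "per_fraction": {str(k): v for k, v in self.per_fraction.items()},
            "v_ref": self.v_ref, "sufficiency": self.sufficiency,
            "failed_fractions": self.failed_fractions,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")


def sufficiency_fraction(fractions, values, v_ref, metric: str,
                         margin: float = 0.05):
    """Smallest fraction whose metric is at least as good as ``v_ref``
    within ``margin`` (direction-aware)."""
    if v_ref is None:
        return None
    for f, v in sorted(zip(fractions, values)):
        if v is None:
            continue
        if metric in SIMILARITY_METRICS:
            if v >= v_ref * (1 - margin):
                return f
        elif metric in DISSIMILARITY_METRICS:
            if v <= v_ref * (1 + margin):
                return f
        else:
            raise ValueError(f"no direction known for metric {metric!r}")
    return None


def downsample_sweep(cm: CountMatrix, axis: str, preset="seurat_like",
                     fractions=(0.01, 0.05, 0.1, 0.25, 0.5, 0.75, 1.0),
                     v_ref: ConcordanceReport = None, seed: int = 0,
                     overrides: dict = None) -> SweepResult:
    """Run a preset on downsampled data across a fraction grid.

    Each fraction's run is compared against the full-size run of the same
    preset; DE is computed with the full-size run's cluster labels
    transferred onto the downsampled cells so marker statistics refer to
    identical clusters.  ``v_ref`` defaults to the seurat_like vs
    scanpy_like comparison at full size.  The sufficiency fraction per
    metric is the smallest grid fraction at least as good as ``v_ref``
    within a 5% margin, direction-aware.
    """
    if axis not in ("reads", "cells"):
        raise ValueError("axis must be 'reads' or 'cells'")
    fractions = sorted(fractions)
    if not all(0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")

    full = run_pipeline(cm, preset, seed=seed, overrides=overrides)
    if v_ref is None:
        ref_a = run_pipeline(cm, "seurat_like", seed=seed, overrides=overrides)
        ref_b = run_pipeline(cm, "scanpy_like", seed=seed, overrides=overrides)
        v_ref = compare_runs(ref_a, ref_b)

    full_cells = full["filter"][0]
    label_of = dict(zip(full_cells, full["cluster"].labels))

    per_fraction, failed = {}, []
    for f in fractions:
        try:
            ds = (downsample_reads(cm, f, seed=seed + 1) if axis == "reads"
                  else downsample_cells(cm, f, seed=seed + 1))
            probe = run_pipeline(cm=ds, preset=preset, seed=seed,
                                 overrides=overrides)
            ds_cells = probe["filter"][0]
            transfer = [label_of.get(c, -1) for c in ds_cells]
            if len(set(transfer)) > 1:
                probe = run_pipeline(cm=ds, preset=preset, seed=seed,
                                     overrides=overrides,
                                     labels_override=transfer)
            rep = compare_runs(full, probe)
            per_fraction[f] = rep.metrics
        except (ValueError, RuntimeError) as exc:
            warnings.warn(f"fraction {f} failed: {exc}", stacklevel=2)
            failed.append(f)
            per_fraction[f] = None

    scalars = SIMILARITY_METRICS | DISSIMILARITY_METRICS
    sufficiency = {}
    for m in sorted(scalars):
        vals = [per_fraction[f][m] if per_fraction[f] else None
                for f in fractions]
        sufficiency[m] = sufficiency_fraction(
            fractions, vals, v_ref.metrics.get(m), m)
    return SweepResult(
        axis=axis, fractions=list(fractions),
        per_fraction=per_fraction,
        v_ref={m: v_ref.metrics.get(m) for m in sorted(scalars)},
        sufficiency=sufficiency, failed_fractions=failed,
    )


def seed_sensitivity(cm: CountMatrix, preset="seurat_like",
                     stage: str = "louvain", seeds=(0, 1), overrides: dict = None):
    """Rerun one nominally stochastic stage across seeds on frozen input.

    Returns one ConcordanceReport per seed pair with the stage-appropriate
    metrics (SNN concordance for ``knn``, ARI for ``louvain``, embedding
    KNN Jaccard for ``embedding``).
    """
    if stage not in ("knn", "louvain", "embedding"):
        raise ValueError(f"stage {stage!r} is not a stochastic stage")
    seeds = list(seeds)
    if len(seeds) < 2:
        raise ValueError("need at least two seeds")
    base = run_pipeline(cm, preset, seed=seeds[0], overrides=overrides)
    cfg = (make_preset(preset, overrides) if isinstance(preset, str)
           else copy.deepcopy(preset))

    outputs = []
    for s in seeds:
        if stage == "knn":
            g = graph.knn_exact(base["pca"], k=base["knn"].k)
            if cfg["snn"]["construction"] == "jaccard_prune":
                g = graph.snn_jaccard_prune(g, prune=cfg["snn"]["prune"])
            else:
                g = graph.snn_undirected_union(g)
            outputs.append(g)
        elif stage == "louvain":
            outputs.append(graph.louvain(
                base["snn"], gamma=cfg["cluster"]["gamma"],
                variant=cfg["cluster"]["variant"], seed=s,
                max_iter=cfg["cluster"].get("max_iter") or 10))
        else:  # embedding: deterministic PC1-2 stand-in, seed has no effect
            outputs.append(base["embedding"])

    reports = []
    for i in range(len(seeds)):
        for j in range(i + 1, len(seeds)):
            metrics = {}
            if stage == "knn":
                mj, mr, _ = cc.snn_concordance(outputs[i].snn, outputs[j].snn)
                metrics = {"snn_median_jaccard": mj,
                           "snn_median_log_degree_ratio": mr}
            elif stage == "louvain":
                metrics = {"ari": cc.ari(outputs[i].labels,
                                         outputs[j].labels)}
            else:
                metrics = {"embedding_knn_median_jaccard":
                           cc.embedding_knn_concordance(
                               outputs[i], outputs[j],
                               k=min(20, outputs[i].shape[0]))}
            reports.append(ConcordanceReport(
                metrics=metrics,
                parameters={"stage": stage,
                            "seeds": [seeds[i], seeds[j]]},
                provenance={"preset": base.provenance.get("preset")},
            ))
    return reports
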