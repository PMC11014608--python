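"""Synthetic count matrices with planted structure, plus downsampling.

Counts are negative-binomial (Gamma-Poisson) draws, the canonical model for
UMI molecule counts.  Each cell belongs to one of ``n_clusters`` planted
groups; a fraction of genes per cluster act as markers whose mean is shifted
by a log-scale effect.  Library-size heterogeneity is log-normal
multiplicative, producing the count-depth variation the normalization stage
must remove.  A configurable fraction of genes is named with a
mitochondrial prefix so that mito-content filtering is exercised.

Read downsampling is emulated by binomial thinning of the UMI counts:
sub-sampling reads thins each molecule's count approximately binomially, so
thinning at the count level reproduces the operation without touching
FASTQs.  Cell downsampling is a uniform row subsample without replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .io_formats import CountMatrix

__all__ = ["SynthConfig", "generate_counts", "downsample_reads", "downsample_cells"]


@dataclass
class SynthConfig:
    """Parameters of the planted-cluster negative-binomial generator.

    Defaults describe a desk-scale dataset: 1000 cells, 800 genes, three
    equally sized clusters, sparse baseline expression (gamma-distributed
    gene means around 2 counts/cell), 10% marker genes per cluster with a
    natural-log effect of 1, moderate overdispersion, and ~40% CV in
    library size.
    """

    n_cells: int = 1000
    n_genes: int = 800
    n_clusters: int = 3
    cluster_proportions: tuple = None  # None -> equal
    baseline_mean: np.ndarray = None   # None -> Gamma(0.8, scale=2.5) draws
    de_fraction: float = 0.1
    de_effect: float = 1.0             # log-scale shift of marker-gene means
    nb_dispersion: float = 2.0         # gamma shape; var = mu + mu^2/disp
    libsize_lognormal_sigma: float = 0.35
    mito_fraction: float = 0.03
    mito_prefix: str = "MT-"
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters > self.n_cells:
            raise ValueError("n_clusters exceeds n_cells")
        if self.cluster_proportions is None:
            self.cluster_proportions = tuple(
                [1.0 / self.n_clusters] * self.n_clusters
            )
        props = np.asarray(self.cluster_proportions, dtype=float)
        if len(props) != self.n_clusters:
            raise ValueError("cluster_proportions length != n_clusters")
        if not np.isclose(props.sum(), 1.0):
            raise ValueError("cluster_proportions must sum to 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must lie in [0, 1]")


def _gene_names(cfg: SynthConfig, rng: np.random.Generator) -> tuple:
    n_mito = int(round(cfg.mito_fraction * cfg.n_genes))
    names = [f"GENE-{i:05d}" for i in range(cfg.n_genes)]
    mito_idx = rng.choice(cfg.n_genes, size=n_mito, replace=False)
    for j, g in enumerate(sorted(mito_idx)):
        names[g] = f"{cfg.mito_prefix}{j:04d}"
    mask = np.zeros(cfg.n_genes, dtype=bool)
    mask[mito_idx] = True
    return names, mask


def generate_counts(cfg: SynthConfig):
    """Draw a planted-cluster count matrix.

    Returns ``(CountMatrix, labels)`` where ``labels`` is the per-cell
    planted cluster id.  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)

    props = np.asarray(cfg.cluster_proportions, dtype=float)
    sizes = np.floor(props * cfg.n_cells).astype(int)
    sizes[: cfg.n_cells - sizes.sum()] += 1  # distribute rounding remainder
    labels = np.repeat(np.arange(cfg.n_clusters), sizes)

    if cfg.baseline_mean is None:
        base = rng.gamma(shape=0.8, scale=2.5, size=cfg.n_genes)
    else:
        base = np.broadcast_to(
            np.asarray(cfg.baseline_mean, dtype=float), (cfg.n_genes,)
        ).copy()

    # log-scale marker effects: per cluster, a disjoint-when-possible slice
    # of genes gets mean * exp(de_effect)
    effect = np.zeros((cfg.n_clusters, cfg.n_genes))
    n_markers = int(round(cfg.de_fraction * cfg.n_genes))
    marker_sets = []
    if n_markers > 0 and cfg.de_effect != 0:
        perm = rng.permutation(cfg.n_genes)
        for c in range(cfg.n_clusters):
            lo = (c * n_markers) % cfg.n_genes
            block = perm[lo: lo + n_markers]
            if len(block) < n_markers:  # wrap around
                block = np.concatenate([block, perm[: n_markers - len(block)]])
            effect[c, block] = cfg.de_effect
            marker_sets.append(np.sort(block))

    libfac = rng.lognormal(
        mean=-0.5 * cfg.libsize_lognormal_sigma ** 2,
        sigma=cfg.libsize_lognormal_sigma,
        size=cfg.n_cells,
    )

    mu = base[None, :] * np.exp(effect)[labels] * libfac[:, None]
    shape = cfg.nb_dispersion
    lam = rng.gamma(shape=shape, scale=mu / shape)
    counts = rng.poisson(lam)

    names, mito_mask = _gene_names(cfg, rng)
    cm = CountMatrix(
        counts=sp.csr_matrix(counts),
        barcodes=[f"CELL-{i:05d}" for i in range(cfg.n_cells)],
        features=names,
        mito_mask=mito_mask,
        provenance={
            "generator": "negative_binomial_planted_clusters",
            "seed": cfg.seed,
            "n_clusters": cfg.n_clusters,
            "de_effect": cfg.de_effect,
            "de_fraction": cfg.de_fraction,
            "marker_genes": [np.asarray(m).tolist() for m in marker_sets],
        },
    )
    return cm, labels


def downsample_reads(cm: CountMatrix, fraction: float, seed: int) -> CountMatrix:
    """Binomially thin every count: X -> Binomial(X, fraction).

    Emulates read subsampling at the UMI-count level; deterministic given
    ``seed``.  ``fraction`` must lie in [0, 1].
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    coo = sp.coo_matrix(cm.counts)
    data = rng.binomial(coo.data.astype(np.int64), fraction)
    thinned = sp.coo_matrix((data, (coo.row, coo.col)), shape=coo.shape)
    thinned.eliminate_zeros()
    prov = dict(cm.provenance)
    prov["read_downsample_fraction"] = fraction
    prov["read_downsample_note"] = (
        "binomial thinning of UMI counts (count-level emulation of read "
        "subsampling)"
    )
    return CountMatrix(
        counts=sp.csr_matrix(thinned),
        barcodes=cm.barcodes,
        features=cm.features,
        mito_mask=cm.mito_mask,
        provenance=prov,
    )


def downsample_cells(cm: CountMatrix, fraction: float, seed: int) -> CountMatrix:
    """Uniform subsample of round(fraction * n_cells) cells, order preserved."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    n_keep = int(round(fraction * cm.n_cells))
    if n_keep == 0:
        raise ValueError("fraction leaves zero cells")
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(cm.n_cells, size=n_keep, replace=False))
    prov = dict(cm.provenance)
    prov["cell_downsample_fraction"] = fraction
    return CountMatrix(
        counts=cm.counts[keep],
        barcodes=[cm.barcodes[i] for i in keep],
        features=cm.features,
        mito_mask=cm.mito_mask,
        provenance=prov,
    )
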