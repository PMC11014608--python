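"""Reading and writing the on-disk formats the toolkit touches.

Count matrices travel as 10x-style MatrixMarket triplets (``matrix.mtx`` +
``barcodes.tsv`` + ``features.tsv``, plain or gzipped).  On disk the 10x
convention is genes x cells; in memory everything is cells x genes, matching
the X_ig notation (cell i, gene g) used throughout the package.  The reader
transposes and records the orientation in provenance.

Concordance reports and run manifests are JSON; cluster labels and DE tables
are CSV (handled in :mod:`sccompare.harness`).
"""

from __future__ import annotations

import gzip
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "ConcordanceReport",
    "FormatError",
    "METRIC_NAMES",
    "read_mtx_triplet",
    "write_mtx_triplet",
    "read_report",
    "write_report",
]


class FormatError(ValueError):
    """Raised when an on-disk file violates the expected format."""


#: Fixed vocabulary of per-stage concordance metrics.
METRIC_NAMES = (
    "jaccard_cells",
    "jaccard_genes",
    "jaccard_hvg",
    "pc_loading_diff",
    "eig_sine",
    "scree_diff",
    "snn_median_jaccard",
    "snn_median_log_degree_ratio",
    "ari",
    "embedding_knn_median_jaccard",
    "jaccard_sig_markers",
    "jaccard_markers",
    "ccc_logfc",
    "p_flip_fraction",
)


@dataclass
class CountMatrix:
    """Sparse nonnegative integer cells x genes matrix with identifiers.

    Attributes
    ----------
    counts : scipy.sparse.csr_matrix
        Integer UMI counts, one row per cell, one column per gene.
    barcodes : list of str
        Unique cell identifiers, one per row.
    features : list of str
        Unique gene identifiers, one per column.
    mito_mask : numpy.ndarray of bool
        Per-gene flag marking mitochondrial genes.
    """

    counts: sp.csr_matrix
    barcodes: list
    features: list
    mito_mask: np.ndarray = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = sp.csr_matrix(self.counts)
        self.barcodes = list(self.barcodes)
        self.features = list(self.features)
        if self.mito_mask is None:
            self.mito_mask = np.zeros(self.counts.shape[1], dtype=bool)
        self.mito_mask = np.asarray(self.mito_mask, dtype=bool)
        self._validate()

    def _validate(self):
        n_cells, n_genes = self.counts.shape
        if len(self.barcodes) != n_cells:
            raise FormatError(
                f"{len(self.barcodes)} barcodes for {n_cells} matrix rows"
            )
        if len(self.features) != n_genes:
            raise FormatError(
                f"{len(self.features)} features for {n_genes} matrix columns"
            )
        if len(set(self.barcodes)) != n_cells:
            raise FormatError("barcodes are not unique")
        if len(set(self.features)) != n_genes:
            raise FormatError("features are not unique")
        if self.mito_mask.shape != (n_genes,):
            raise FormatError("mito_mask length does not match gene count")
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise FormatError("negative count entry")
            if not np.allclose(data, np.round(data)):
                raise FormatError("non-integral count entry")
        self.counts.data = np.asarray(np.round(data), dtype=np.int64)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def set_mito_by_prefix(self, prefix: str = "MT-") -> None:
        """Flag mitochondrial genes by identifier prefix (default ``MT-``)."""
        self.mito_mask = np.array(
            [f.upper().startswith(prefix.upper()) for f in self.features],
            dtype=bool,
        )

    def equals(self, other: "CountMatrix") -> bool:
        return (
            self.barcodes == other.barcodes
            and self.features == other.features
            and (self.counts != other.counts).nnz == 0
        )


def _open_maybe_gzip(path, mode="rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _read_id_column(path):
    """First whitespace-separated column of a (possibly gzipped) TSV."""
    with _open_maybe_gzip(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_mtx_triplet(matrix_path, barcodes_path, features_path,
                     mito_prefix: str = "MT-") -> CountMatrix:
    """Read a 10x-style MTX triplet into a :class:`CountMatrix`.

    The on-disk matrix is genes x cells (10x convention) and is transposed
    to cells x genes in memory.  Duplicate coordinate entries are summed.
    Coordinates are 1-based on disk (MatrixMarket), 0-based in memory.
    """
    try:
        with _open_maybe_gzip(matrix_path, "rb") as fh:
            mat = scipy.io.mmread(fh)
    except Exception as exc:  # noqa: BLE001 - re-raise with format context
        raise FormatError(f"cannot parse MatrixMarket file: {exc}") from exc
    mat = sp.coo_matrix(mat)
    barcodes = _read_id_column(barcodes_path)
    features = _read_id_column(features_path)
    if mat.shape != (len(features), len(barcodes)):
        raise FormatError(
            f"MTX header {mat.shape} does not match "
            f"{len(features)} features x {len(barcodes)} barcodes"
        )
    if mat.data.size and np.any(mat.data < 0):
        raise FormatError("negative count entry in MTX")
    if mat.data.size and not np.allclose(mat.data, np.round(mat.data)):
        raise FormatError("non-integral count entry in MTX")
    cm = CountMatrix(
        counts=sp.csr_matrix(mat.T),  # duplicate coordinates summed here
        barcodes=barcodes,
        features=features,
        provenance={"orientation_on_disk": "genes_x_cells",
                    "source": str(matrix_path)},
    )
    cm.set_mito_by_prefix(mito_prefix)
    return cm


def write_mtx_triplet(cm: CountMatrix, dir_path) -> dict:
    """Write ``matrix.mtx``, ``barcodes.tsv`` and ``features.tsv``.

    Returns the mapping of role -> written path.  The matrix is written
    genes x cells to round-trip through :func:`read_mtx_triplet`.
    """
    os.makedirs(dir_path, exist_ok=True)
    paths = {
        "matrix": os.path.join(dir_path, "matrix.mtx"),
        "barcodes": os.path.join(dir_path, "barcodes.tsv"),
        "features": os.path.join(dir_path, "features.tsv"),
    }
    scipy.io.mmwrite(paths["matrix"], sp.coo_matrix(cm.counts.T), field="integer")
    with open(paths["barcodes"], "w") as fh:
        fh.writelines(b + "\n" for b in cm.barcodes)
    with open(paths["features"], "w") as fh:
        fh.writelines(f + "\n" for f in cm.features)
    return paths


@dataclass
class ConcordanceReport:
    """Named per-stage similarity metrics for one pair of runs.

    ``metrics`` maps a name from :data:`METRIC_NAMES` to a float, a list of
    floats (per-PC metrics), or ``None`` for an explicitly missing metric.
    """

    metrics: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        for key in self.metrics:
            if key not in METRIC_NAMES:
                raise FormatError(f"unknown metric key: {key!r}")
        for key, val in self.metrics.items():
            if val is None:
                continue
            vals = val if isinstance(val, (list, tuple)) else [val]
            for v in vals:
                if not math.isfinite(float(v)):
                    raise FormatError(f"non-finite value for metric {key!r}")

    def __getitem__(self, key):
        return self.metrics[key]


def write_report(report: ConcordanceReport, path) -> None:
    payload = {
        "metrics": report.metrics,
        "parameters": report.parameters,
        "provenance": report.provenance,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_report(path) -> ConcordanceReport:
    with open(path) as fh:
        payload = json.load(fh)
    return ConcordanceReport(
        metrics=payload.get("metrics", {}),
        parameters=payload.get("parameters", {}),
        provenance=payload.get("provenance", {}),
    )
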