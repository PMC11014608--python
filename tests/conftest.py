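import numpy as np
import pytest

import sccompare as sc

# Desk-scale study conditions shared by the integration-level tests:
# three strongly separated planted clusters (240 cells, 200 genes, 20%
# marker genes shifted by e^2), with filtering thresholds matched to the
# synthetic gene count.
SYNTH = dict(n_cells=240, n_genes=200, n_clusters=3,
             de_effect=2.0, de_fraction=0.2, seed=1)
OVERRIDES = {
    "filter": {"min_genes_per_cell": 30, "min_umi": 50, "max_mito_pct": 50.0},
    "hvg": {"top_n": 60},
}


@pytest.fixture(scope="session")
def planted():
    """(CountMatrix, true labels) with strongly separated clusters."""
    cm, labels = sc.generate_counts(sc.SynthConfig(**SYNTH))
    return cm, labels


@pytest.fixture(scope="session")
def desk_overrides():
    return OVERRIDES


@pytest.fixture(scope="session")
def paired_runs(planted):
    """One run per preset on the planted data, shared across tests."""
    cm, _ = planted
    a = sc.run_pipeline(cm, "seurat_like", seed=0, overrides=OVERRIDES)
    b = sc.run_pipeline(cm, "scanpy_like", seed=0, overrides=OVERRIDES)
    return a, b


@pytest.fixture()
def tiefree_nm():
    """A small NormMatrix whose values are almost surely tie-free."""
    rng = np.random.default_rng(7)
    Y = rng.uniform(0.01, 5.0, size=(60, 40))
    return sc.NormMatrix(
        Y=Y, size_factor=np.ones(60),
        barcodes=[f"C{i}" for i in range(60)],
        features=[f"G{j}" for j in range(40)],
    )


@pytest.fixture()
def tiefree_labels():
    rng = np.random.default_rng(8)
    return rng.integers(0, 3, size=60)
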