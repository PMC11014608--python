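import numpy as np
import pytest
import scipy.sparse as sp

import sccompare as sc
from sccompare.preprocess import loess_fit


def _cm(dense, features=None, mito=None):
    dense = np.asarray(dense)
    return sc.CountMatrix(
        counts=sp.csr_matrix(dense),
        barcodes=[f"B{i}" for i in range(dense.shape[0])],
        features=features or [f"G{j}" for j in range(dense.shape[1])],
        mito_mask=mito,
    )


class TestFilter:
    def test_sparse_cell_and_rare_gene_removed(self):
        X = np.zeros((3, 4), dtype=int)
        X[0] = [5, 5, 5, 0]   # 3 genes detected
        X[1] = [4, 4, 4, 4]   # 4 genes
        X[2, 0] = 9           # 1 gene -> removed at min_genes=3
        out = sc.filter_cells_genes(_cm(X), min_genes_per_cell=3,
                                    min_cells_per_gene=2)
        assert out.barcodes == ["B0", "B1"]
        # gene G3 detected in 1 remaining cell only -> removed
        assert out.features == ["G0", "G1", "G2"]

    def test_mito_threshold_hand_case(self):
        # cell 0: 30 mito of 100 total = 30%
        X = np.array([[30, 70], [5, 95]])
        mito = np.array([True, False])
        kept = sc.filter_cells_genes(_cm(X, mito=mito), min_genes_per_cell=1,
                                     min_cells_per_gene=1, max_mito_pct=35)
        assert kept.barcodes == ["B0", "B1"]
        kept = sc.filter_cells_genes(_cm(X, mito=mito), min_genes_per_cell=1,
                                     min_cells_per_gene=1, max_mito_pct=20)
        assert kept.barcodes == ["B1"]

    def test_all_cells_removed_reports_casualties(self):
        X = np.eye(3, dtype=int)
        with pytest.raises(ValueError, match="casualties|removed"):
            sc.filter_cells_genes(_cm(X), min_genes_per_cell=5)


class TestNormalize:
    def test_hand_value(self):
        nm = sc.normalize_cp10k(_cm([[2, 1, 1], [1, 1, 1]]))
        # S = 4/1e4 for cell 0; gene 0: ln(2/(4e-4) + 1) = ln(5001)
        assert nm.Y[0, 0] == pytest.approx(np.log(5001.0), abs=1e-12)
        assert nm.Y.min() >= 0

    def test_zero_counts_map_to_zero_and_sum_invariant(self, planted):
        cm, _ = planted
        f = sc.filter_cells_genes(cm, min_genes_per_cell=10,
                                  min_cells_per_gene=1)
        nm = sc.normalize_cp10k(f)
        assert np.all(nm.Y[f.counts.toarray() == 0] == 0)
        sums = np.expm1(nm.Y).sum(axis=1)
        assert np.allclose(sums, 10_000.0, rtol=1e-6)

    def test_zero_total_cell_errors(self):
        with pytest.raises(ZeroDivisionError):
            sc.normalize_cp10k(_cm([[0, 0], [1, 1]]))


class TestHVGBinned:
    def _nm(self, Y):
        Y = np.asarray(Y, float)
        return sc.NormMatrix(Y=Y, size_factor=np.ones(Y.shape[0]),
                             barcodes=[f"B{i}" for i in range(Y.shape[0])],
                             features=[f"G{j}" for j in range(Y.shape[1])])

    def test_identical_genes_tie_to_index_order(self):
        col = np.linspace(0.1, 2.0, 10)
        Y = np.tile(col[:, None], (1, 6))
        res = sc.hvg_binned_dispersion(self._nm(Y), n_bins=1, top_n=2)
        assert len(set(res.norm_dispersion.round(12))) == 1
        assert res.selected == ["G0", "G1"]

    def test_inflated_variance_gene_wins(self):
        rng = np.random.default_rng(0)
        Y = rng.uniform(1.0, 2.0, size=(10, 50))
        Y[:, 0] = 1.5 + 3.0 * (Y[:, 0] - 1.5)  # same mean, 9x variance
        res = sc.hvg_binned_dispersion(self._nm(Y), n_bins=1, top_n=1)
        assert res.selected == ["G0"]
        assert np.argmax(res.norm_dispersion) == 0

    def test_zero_variance_gene_excluded(self):
        Y = np.column_stack([np.full(8, 2.0), np.linspace(0.5, 3, 8),
                             np.linspace(1, 2, 8)])
        res = sc.hvg_binned_dispersion(self._nm(Y), n_bins=1, top_n=2)
        assert res.dispersion[0] == 0
        assert "G0" not in res.selected

    def test_gene_order_invariance(self, planted, desk_overrides):
        cm, _ = planted
        f = sc.filter_cells_genes(cm, **desk_overrides["filter"])
        nm = sc.normalize_cp10k(f)
        res = sc.hvg_binned_dispersion(nm, top_n=40)
        perm = np.random.default_rng(1).permutation(nm.n_genes)
        nm_p = sc.NormMatrix(Y=nm.Y[:, perm], size_factor=nm.size_factor,
                             barcodes=nm.barcodes,
                             features=[nm.features[j] for j in perm])
        res_p = sc.hvg_binned_dispersion(nm_p, top_n=40)
        assert set(res.selected) == set(res_p.selected)


class TestHVGLoessVST:
    def test_collinear_scaled_genes_with_variance_outlier(self):
        """Genes that are scaled copies of one pattern have exactly
        collinear (log10 mean, log10 var); a same-mean gene with inflated
        variance ranks first."""
        base = np.array([1, 1, 1, 1, 3, 3, 3, 3] * 3)
        outlier = np.array([0, 0, 0, 0, 4, 4, 4, 4] * 3)  # mean 2, 4x var
        cols = [c * base for c in (1, 2, 3, 4, 6, 8, 12, 16)] + [outlier]
        X = np.column_stack(cols)
        cm = _cm(X)
        res = sc.hvg_loess_vst(cm, top_n=1, clip=None)
        assert res.selected == [cm.features[len(cols) - 1]]
        # scaled copies of the trend all standardize to ~the same variance
        sv = res.standardized_variance[:-1]
        assert sv.std() / sv.mean() < 0.2

    def test_identical_genes_tie(self):
        rng = np.random.default_rng(2)
        col = rng.integers(0, 9, 12)
        col2 = rng.integers(1, 14, 12)
        X = np.column_stack([col, col, col2])
        res = sc.hvg_loess_vst(_cm(X), top_n=3)
        assert res.standardized_variance[0] == pytest.approx(
            res.standardized_variance[1])

    def test_clip_only_affects_large_deviations(self, planted):
        cm, _ = planted
        f = sc.filter_cells_genes(cm, min_genes_per_cell=10,
                                  min_cells_per_gene=3)
        r_inf = sc.hvg_loess_vst(f, top_n=30, clip=None)
        r_clip = sc.hvg_loess_vst(f, top_n=30)  # clip = sqrt(n)
        X = f.counts.toarray()
        z_max = np.zeros(f.n_genes)
        m = r_inf.predicted_variance > 0
        z_max[m] = ((X[:, m] - r_inf.mean[m])
                    / np.sqrt(r_inf.predicted_variance[m])).max(axis=0)
        differs = ~np.isclose(r_inf.standardized_variance,
                              r_clip.standardized_variance)
        assert np.all(z_max[differs] > np.sqrt(f.n_cells))

    def test_loess_reproduces_collinear_points(self):
        x = np.linspace(0, 3, 25)
        y = 2.0 * x - 1.0
        assert np.allclose(loess_fit(x, y, span=0.3, degree=2), y,
                           atol=1e-8)

    def test_top_n_too_large_rejected(self):
        with pytest.raises(ValueError):
            sc.hvg_loess_vst(_cm(np.eye(4, dtype=int)), top_n=9)


class TestScaleRegress:
    def _nm(self, Y):
        Y = np.asarray(Y, float)
        return sc.NormMatrix(Y=Y, size_factor=np.ones(Y.shape[0]),
                             barcodes=[f"B{i}" for i in range(Y.shape[0])],
                             features=[f"G{j}" for j in range(Y.shape[1])])

    def test_unit_variance_zero_mean(self):
        rng = np.random.default_rng(4)
        M, _, zv = sc.scale_and_regress(self._nm(rng.gamma(2, 1, (40, 7))))
        assert np.allclose(M.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(M.var(axis=0), 1, atol=1e-8)
        assert not zv.any()

    def test_regressing_gene_on_itself_flags_zero_variance(self):
        rng = np.random.default_rng(5)
        Y = rng.uniform(0, 2, (30, 3))
        M, _, zv = sc.scale_and_regress(self._nm(Y), genes=["G0"],
                                        covariates=Y[:, [0]])
        assert zv[0]
        assert np.all(M[:, 0] == 0)

    def test_clip_max_hand_case(self):
        # one far outlier: z-scores exceed 10, clipped to exactly 10
        v = np.array([0.0, 0.0, 0.0, 0.0, 1000.0] + [0.0] * 120)
        M, _, _ = sc.scale_and_regress(self._nm(v[:, None]), clip_max=10)
        assert M.max() == pytest.approx(10.0)

    def test_regression_removes_covariate_signal(self):
        rng = np.random.default_rng(6)
        cov = rng.uniform(1, 3, 50)
        Y = np.outer(cov, np.ones(4)) + rng.normal(0, 0.1, (50, 4))
        M, _, _ = sc.scale_and_regress(self._nm(np.abs(Y)),
                                       covariates=cov[:, None])
        corr = [abs(np.corrcoef(M[:, j], cov)[0, 1]) for j in range(4)]
        assert max(corr) < 0.05


class TestPCA:
    def test_single_direction_explains_everything(self):
        t = np.linspace(-1, 1, 30)
        X = np.outer(t, [1.0, 2.0, -0.5])
        with pytest.warns(UserWarning):
            p = sc.pca_top_k(X, K=2)
        assert p.variance_explained[0] == pytest.approx(1.0)

    def test_matches_dense_eigendecomposition(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(5, 4))
        p = sc.pca_top_k(X, K=4)
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc / 4)
        evals, evecs = evals[::-1], evecs[:, ::-1]
        assert np.allclose(p.variance_explained,
                           evals / evals.sum(), atol=1e-8)
        for k in range(4):
            dot = abs(float(p.loadings[:, k] @ evecs[:, k]))
            assert dot == pytest.approx(1.0, abs=1e-8)
        # embeddings reproduce the centered data
        assert np.allclose(p.embeddings @ p.loadings.T, Xc, atol=1e-8)

    def test_duplicating_cells_leaves_loadings_unchanged(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(20, 6))
        p1 = sc.pca_top_k(X, K=3)
        p2 = sc.pca_top_k(np.vstack([X, X]), K=3)
        assert np.allclose(np.abs(p1.loadings), np.abs(p2.loadings),
                           atol=1e-8)

    def test_variance_explained_monotone_and_bounded(self, paired_runs):
        p = paired_runs[0]["pca"]
        ve = p.variance_explained
        assert np.all(np.diff(ve) <= 1e-12)
        assert 0 < ve.sum() <= 1 + 1e-12

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            sc.pca_top_k(np.zeros((4, 10)), K=5)
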