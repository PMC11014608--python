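import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import sccompare as sc
from sccompare.diffexp import DETable


def _nm(Y, log_base=np.e):
    Y = np.asarray(Y, float)
    return sc.NormMatrix(Y=Y, size_factor=np.ones(Y.shape[0]),
                         barcodes=[f"B{i}" for i in range(Y.shape[0])],
                         features=[f"G{j}" for j in range(Y.shape[1])],
                         log_base=log_base)


def exact_rank_sum_p(x, y):
    """Exact two-sided rank-sum p by enumeration over group assignments."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        w = ranks[list(comb)].sum()
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / total


class TestWilcoxon:
    def test_hand_normal_approximation(self):
        """[1,2,3] vs [4,5,6]: W=6, mu=10.5, sigma=sqrt(5.25),
        z ~ -1.964, p ~ 0.0495; exact enumeration gives 0.1, confirming
        the expected approximation gap at tiny n."""
        Y = np.array([[1], [2], [3], [4], [5], [6]], float)
        labels = [0, 0, 0, 1, 1, 1]
        out = sc.wilcoxon_one_vs_rest(_nm(Y), labels, tie_correct=True)
        row = out[out.cluster == 0].iloc[0]
        assert row.z == pytest.approx(-4.5 / np.sqrt(5.25), abs=1e-4)
        assert row.z == pytest.approx(-1.964, abs=1e-3)
        assert row.p == pytest.approx(0.0495, abs=1e-3)
        assert exact_rank_sum_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_matches_scipy_and_exact_enumeration_without_ties(self):
        """Without ties the z/p agree exactly with scipy's asymptotic
        rank-sum test, and track the exact enumerated null within the
        usual small-n approximation error."""
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 5), rng.normal(1.2, 1, 6)
        Y = np.abs(np.concatenate([x, y]))[:, None]
        labels = [0] * 5 + [1] * 6
        out = sc.wilcoxon_one_vs_rest(_nm(Y), labels, tie_correct=True)
        row = out[out.cluster == 0].iloc[0]
        z_ref, p_ref = stats.ranksums(Y[:5, 0], Y[5:, 0])
        assert row.z == pytest.approx(z_ref, abs=1e-12)
        assert row.p == pytest.approx(p_ref, abs=1e-12)
        exact_p = exact_rank_sum_p(Y[:5, 0], Y[5:, 0])
        assert abs(row.p - exact_p) < 0.1

    def test_tie_correction_no_op_without_ties(self, tiefree_nm,
                                               tiefree_labels):
        a = sc.wilcoxon_one_vs_rest(tiefree_nm, tiefree_labels, True)
        b = sc.wilcoxon_one_vs_rest(tiefree_nm, tiefree_labels, False)
        assert np.allclose(a.p, b.p) and np.allclose(a.z, b.z)

    def test_tie_correction_changes_p_with_ties(self):
        Y = np.array([[0], [0], [0], [0], [1], [1], [1], [2]], float)
        labels = [0, 0, 0, 0, 1, 1, 1, 1]
        a = sc.wilcoxon_one_vs_rest(_nm(Y), labels, True)
        b = sc.wilcoxon_one_vs_rest(_nm(Y), labels, False)
        assert a.iloc[0].p < b.iloc[0].p  # correction shrinks the variance

    def test_constant_gene_gets_p_one(self):
        Y = np.column_stack([np.ones(6), np.arange(6.0)])
        out = sc.wilcoxon_one_vs_rest(_nm(Y), [0, 0, 0, 1, 1, 1], True)
        assert np.all(out[out.gene == "G0"].p == 1.0)

    def test_label_swap_negates_z(self, tiefree_nm, tiefree_labels):
        two = np.where(np.asarray(tiefree_labels) == 0, 0, 1)
        a = sc.wilcoxon_one_vs_rest(tiefree_nm, two, True)
        za = a[a.cluster == 0].z.to_numpy()
        zb = a[a.cluster == 1].z.to_numpy()
        assert np.allclose(za, -zb)
        assert np.allclose(a[a.cluster == 0].p.to_numpy(),
                           a[a.cluster == 1].p.to_numpy())


class TestLogFC:
    def _groups_nm(self, m1, m2, n1, n2):
        """NormMatrix with one gene: group1 has expm1(Y)=m1, group2 m2."""
        Y = np.concatenate([np.full(n1, np.log1p(m1)),
                            np.full(n2, np.log1p(m2))])[:, None]
        nm = _nm(Y)
        return nm, np.arange(n1), np.arange(n1, n1 + n2)

    def test_pseudocount_worked_example_seurat_v5(self):
        nm, g1, g2 = self._groups_nm(0.0, 1.0, 100, 10_000)
        val = sc.logfc(nm, g1, g2, formula="seurat_v5")[0]
        # log2(0.01 / (1 + 1e-4)) ~ log2(0.01) ~ -6.6
        assert round(val, 1) == -6.6

    def test_pseudocount_worked_example_scanpy(self):
        nm, g1, g2 = self._groups_nm(0.0, 1.0, 100, 10_000)
        val = sc.logfc(nm, g1, g2, formula="scanpy")[0]
        # log2(1e-9 / (1 + 1e-9)) ~ -29.90
        assert round(val, 2) == -29.90

    def test_seurat_v4_unit_pseudocount(self):
        nm, g1, g2 = self._groups_nm(0.0, 1.0, 10, 10)
        assert sc.logfc(nm, g1, g2, formula="seurat_v4")[0] == (
            pytest.approx(-1.0))

    def test_equal_means_equal_sizes_zero_under_every_formula(self):
        nm, g1, g2 = self._groups_nm(2.0, 2.0, 20, 20)
        for formula in ("reference", "seurat_v5", "seurat_v4", "scanpy"):
            assert sc.logfc(nm, g1, g2, formula=formula)[0] == (
                pytest.approx(0.0, abs=1e-12))

    def test_monotone_in_group_mean(self):
        for formula in ("reference", "seurat_v5", "seurat_v4", "scanpy"):
            vals = []
            for m1 in (0.0, 0.5, 1.0, 3.0, 10.0):
                nm, g1, g2 = self._groups_nm(m1, 2.0, 15, 25)
                vals.append(sc.logfc(nm, g1, g2, formula=formula)[0])
            assert np.all(np.diff(vals) > 0)

    def test_v4_equals_v5_only_for_single_cell_groups(self):
        nm, g1, g2 = self._groups_nm(3.0, 1.0, 1, 1)
        assert sc.logfc(nm, g1, g2, "seurat_v4")[0] == pytest.approx(
            sc.logfc(nm, g1, g2, "seurat_v5")[0])
        # larger pseudocount shrinks |logFC| toward 0
        for n1, n2, m1, m2 in [(5, 9, 4.0, 1.0), (30, 20, 0.0, 2.0),
                               (8, 8, 6.0, 0.5)]:
            nm, g1, g2 = self._groups_nm(m1, m2, n1, n2)
            v5 = sc.logfc(nm, g1, g2, "seurat_v5")[0]
            v4 = sc.logfc(nm, g1, g2, "seurat_v4")[0]
            assert abs(v5) >= abs(v4)

    def test_scanpy_matches_reference_on_homogeneous_groups(self):
        """When all cells in a group share one value, the geometric and
        arithmetic means coincide and the formulas agree."""
        nm, g1, g2 = self._groups_nm(2.5, 0.8, 12, 18)
        ref = sc.logfc(nm, g1, g2, "reference")[0]
        spy = sc.logfc(nm, g1, g2, "scanpy")[0]
        assert spy == pytest.approx(ref, abs=1e-6)

    def test_empty_group_rejected(self):
        nm, g1, g2 = self._groups_nm(1.0, 1.0, 4, 4)
        with pytest.raises(ValueError):
            sc.logfc(nm, np.array([], dtype=int), g2)


class TestAdjustP:
    def test_bonferroni_scales_by_m(self):
        assert sc.adjust_p([0.01], "bonferroni", m=10)[0] == (
            pytest.approx(0.1))

    def test_bh_hand_step_up(self):
        out = sc.adjust_p([0.01, 0.02, 0.03, 0.04], "bh", m=4)
        assert np.allclose(out, 0.04)

    def test_bonferroni_dominates_bh(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(2, 40))
            assert np.all(sc.adjust_p(p, "bonferroni")
                          >= sc.adjust_p(p, "bh") - 1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(6)
        p = rng.uniform(size=25)
        assert np.allclose(sc.adjust_p(p, "bh"),
                           multipletests(p, method="fdr_bh")[1])
        assert np.allclose(sc.adjust_p(p, "bonferroni"),
                           multipletests(p, method="bonferroni")[1])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            sc.adjust_p([1.5], "bh")


class TestMarkerFilter:
    def _det(self, rows):
        df = pd.DataFrame(rows, columns=["cluster", "gene", "logfc", "z",
                                         "p", "p_adj", "pct_in", "pct_out",
                                         "passed_filter"])
        return DETable(table=df, formula="seurat_v5", adjust="bonferroni",
                       tie_correct=True)

    def test_disabled_filters_pass_everything(self):
        det = self._det([(0, "G0", 0.0, 0, 1.0, 1.0, 0.0, 0.0, True)])
        out = sc.marker_filter(det, 0, 0, 1.01)
        assert out.table.passed_filter.all()

    def test_pct_threshold_hand_case(self):
        det = self._det([(0, "G0", 5.0, 3, 0.001, 0.001, 0.005, 0.002,
                          True)])
        assert not sc.marker_filter(det, min_pct=0.01).table.iloc[0
                                                                  ].passed_filter
        assert sc.marker_filter(det, min_pct=0.001).table.iloc[0
                                                               ].passed_filter

    def test_v5_defaults_pass_superset_of_v4_defaults(self):
        rng = np.random.default_rng(7)
        rows = [(0, f"G{i}", rng.normal(0, 1), 0, 0.01, rng.uniform(0, 0.2),
                 rng.uniform(0, 0.5), rng.uniform(0, 0.5), True)
                for i in range(200)]
        det = self._det(rows)
        v5 = sc.marker_filter(det, 0.01, 0.1, 0.05)
        v4 = sc.marker_filter(det, 0.1, 0.25, 0.05)
        assert set(v4.table[v4.table.passed_filter].gene) <= set(
            v5.table[v5.table.passed_filter].gene)


class TestRunDE:
    def test_presets_differ_only_through_the_four_toggles(self, tiefree_nm,
                                                          tiefree_labels):
        """Starting from the Scanpy-style preset and flipping tie
        correction, logFC formula, adjustment and filtering to the
        Seurat-style choices reproduces the Seurat-style preset exactly."""
        seurat = sc.run_de(tiefree_nm, tiefree_labels, preset="seurat_v5")
        flipped = sc.run_de(
            tiefree_nm, tiefree_labels, preset="scanpy_default",
            tie_correct=True, formula="seurat_v5", adjust="bonferroni",
            filter_params={"min_pct": 0.01, "logfc_threshold": 0.1,
                           "p_threshold": 0.05, "only_pos": False})
        for col in ("logfc", "z", "p", "p_adj", "passed_filter"):
            assert np.allclose(seurat.table[col], flipped.table[col])

    def test_identical_when_all_divergences_removed(self, tiefree_nm,
                                                    tiefree_labels):
        a = sc.run_de(tiefree_nm, tiefree_labels, preset="seurat_v5",
                      formula="reference", filter_params={})
        b = sc.run_de(tiefree_nm, tiefree_labels, preset="scanpy_default",
                      tie_correct=True, formula="reference",
                      adjust="bonferroni", filter_params={})
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_scanpy_default_keeps_every_pair(self, tiefree_nm,
                                             tiefree_labels):
        det = sc.run_de(tiefree_nm, tiefree_labels, preset="scanpy_default")
        n_clusters = len(set(np.asarray(tiefree_labels)))
        assert len(det.table) == n_clusters * tiefree_nm.n_genes
        assert det.table.passed_filter.all()

    def test_p_adj_dominates_p(self, tiefree_nm, tiefree_labels):
        for preset in ("seurat_v5", "scanpy_default"):
            det = sc.run_de(tiefree_nm, tiefree_labels, preset=preset)
            assert np.all(det.table.p_adj >= det.table.p - 1e-12)
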