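"""QC filtering, normalization, overdispersion ranking and kNN smoothing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import crestflow as cf
from crestflow.qc import ExpressionMatrix, QCThresholds


def toy_matrix():
    """Six cells hitting each side of every QC criterion.

    Columns: ok, low transcripts, high transcripts, few genes, many genes
    (only vs a tight max_genes), high ERCC.
    """
    genes = [f"g{i}" for i in range(4)] + ["ERCC-1"]
    values = np.array(
        [
            #  ok  lowT  hiT  fewG  ok2  hiE
            [30, 2, 500, 100, 30, 30],
            [30, 2, 500, 0, 30, 30],
            [30, 2, 500, 0, 30, 30],
            [30, 2, 500, 0, 30, 30],
            [10, 1, 10, 10, 10, 100],  # ERCC row
        ]
    )
    return ExpressionMatrix(values, genes, [f"c{i}" for i in range(6)],
                            np.array([False] * 4 + [True]))


class TestFilterCells:
    def test_each_criterion_excludes_the_right_cell(self):
        m = toy_matrix()
        th = QCThresholds(
            min_transcripts=50, max_transcripts=1000,
            min_genes=2, max_genes=10, max_ercc_fraction=0.15,
        )
        kept, report = cf.filter_cells(m, th)
        assert kept == ["c0", "c4"]
        r = report.set_index("cell_id")
        assert r.loc["c1", "reason"] == "transcripts"
        assert r.loc["c2", "reason"] == "transcripts"
        assert r.loc["c3", "reason"] == "genes"
        assert "ercc_fraction" in r.loc["c5", "reason"]

    def test_gene_count_lower_bound(self):
        # a cell detecting 800 genes is excluded at the default min of 1000
        ng = 900
        values = np.zeros((ng, 1), dtype=int)
        values[:800, 0] = 100
        m = ExpressionMatrix(values, [f"g{i}" for i in range(ng)], ["c0"],
                             np.zeros(ng, bool))
        kept, report = cf.filter_cells(m)
        assert kept == [] and report.loc[0, "genes"] == 800

    def test_ercc_fraction_bound(self):
        values = np.array([[80000], [20000]])
        m = ExpressionMatrix(values, ["g0", "ERCC-0"], ["c0"],
                             np.array([False, True]))
        kept, report = cf.filter_cells(
            m, QCThresholds(0, 1e9, 0, 10**9, max_ercc_fraction=0.15)
        )
        assert kept == [] and report.loc[0, "ercc_fraction"] == pytest.approx(0.2)

    def test_vacuous_thresholds_keep_everything(self):
        m = toy_matrix()
        kept, _ = cf.filter_cells(m, QCThresholds(0, np.inf, 0, 10**9, 1.0))
        assert kept == m.cell_ids

    def test_requires_counts_layer(self):
        m = toy_matrix()
        norm = cf.normalize_log(m)
        with pytest.raises(ValueError, match="counts"):
            cf.filter_cells(norm)


class TestNormalizeLog:
    def test_single_gene_closed_form(self):
        m = ExpressionMatrix(np.array([[123]]), ["g0"], ["c0"], np.array([False]))
        out = cf.normalize_log(m, target_sum=1e6)
        assert out.values[0, 0] == pytest.approx(np.log10(1 + 1e6))

    def test_proportional_cells_identical(self):
        vals = np.array([[10, 30], [20, 60], [5, 15]])
        m = ExpressionMatrix(vals, ["a", "b", "c"], ["c0", "c1"], np.zeros(3, bool))
        out = cf.normalize_log(m)
        np.testing.assert_allclose(out.values[:, 0], out.values[:, 1])

    def test_zero_gene_stays_zero(self):
        vals = np.array([[0, 0], [5, 9]])
        m = ExpressionMatrix(vals, ["z", "b"], ["c0", "c1"], np.zeros(2, bool))
        out = cf.normalize_log(m)
        np.testing.assert_array_equal(out.values[0], 0.0)

    def test_zero_total_cell_dropped_with_warning(self):
        vals = np.array([[5, 0]])
        m = ExpressionMatrix(vals, ["a"], ["c0", "c1"], np.zeros(1, bool))
        with pytest.warns(UserWarning, match="zero-total"):
            out = cf.normalize_log(m)
        assert out.cell_ids == ["c0"]

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_preserves_within_cell_rank_order(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.integers(0, 1000, size=(20, 4))
        m = ExpressionMatrix(vals, [f"g{i}" for i in range(20)],
                             [f"c{i}" for i in range(4)], np.zeros(20, bool))
        if (vals.sum(axis=0) == 0).any():
            return
        out = cf.normalize_log(m)
        for c in range(4):
            assert np.array_equal(
                np.argsort(vals[:, c], kind="mergesort"),
                np.argsort(out.values[:, c], kind="mergesort"),
            )


class TestSelectOverdispersed:
    def _matrix(self, vals):
        ng = vals.shape[0]
        return ExpressionMatrix(vals, [f"g{i}" for i in range(ng)],
                                [f"c{i}" for i in range(vals.shape[1])],
                                np.zeros(ng, bool), layer="log")

    def test_planted_high_variance_gene_ranks_first(self):
        rng = np.random.default_rng(0)
        base = rng.normal(5, 1, size=(30, 200))
        base[7] = rng.normal(5, np.sqrt(10), size=200)  # 10x variance, equal mean
        out = cf.select_overdispersed(self._matrix(base), n_top=5)
        assert out.loc[0, "gene_id"] == "g7"

    def test_constant_gene_never_selected(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(5, 1, size=(15, 100))
        vals[3] = 2.0
        out = cf.select_overdispersed(self._matrix(vals), n_top=15)
        assert "g3" not in out["gene_id"].tolist()

    def test_output_length_contract(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(5, 1, size=(40, 100))
        out = cf.select_overdispersed(self._matrix(vals), n_top=3)
        assert len(out) == 3
        with pytest.warns(UserWarning, match="n_top"):
            out_all = cf.select_overdispersed(self._matrix(vals), n_top=100)
        assert len(out_all) == (out_all["residual"] > 0).sum()


class TestKnnSmooth:
    def _setup(self, seed=0, n=60):
        rng = np.random.default_rng(seed)
        emb = rng.normal(size=(n, 2))
        vals = rng.normal(size=(10, n))
        m = ExpressionMatrix(vals, [f"g{i}" for i in range(10)],
                             [f"c{i}" for i in range(n)], np.zeros(10, bool),
                             layer="log")
        return m, cf.build_knn_graph(emb, n_neighbors=15)

    def test_zero_steps_identity(self):
        m, g = self._setup()
        out = cf.knn_smooth(m, g, steps=0)
        np.testing.assert_array_equal(out.values, m.values)
        assert out.layer == "imputed"

    def test_constant_gene_unchanged(self):
        m, g = self._setup()
        m.values[0] = 3.14
        out = cf.knn_smooth(m, g, steps=4)
        np.testing.assert_allclose(out.values[0], 3.14)

    def test_noise_variance_shrinks(self):
        m, g = self._setup(seed=3)
        out = cf.knn_smooth(m, g, steps=3)
        assert np.all(out.values.var(axis=1) < m.values.var(axis=1))

    def test_linearity(self):
        m, g = self._setup(seed=4)
        x, y = m.values[0], m.values[1]
        combo = m.values.copy()
        combo[2] = 2.0 * x - 0.5 * y
        m2 = ExpressionMatrix(combo, m.gene_ids, m.cell_ids, m.ercc_mask, layer="log")
        out = cf.knn_smooth(m2, g, steps=2)
        np.testing.assert_allclose(
            out.values[2], 2.0 * out.values[0] - 0.5 * out.values[1], atol=1e-10
        )
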