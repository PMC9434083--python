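"""Fork interaction test, branch assignment and activation-rate timing."""

import numpy as np
import pandas as pd
import pytest

import crestflow as cf
from crestflow.bifurcation import activation_timing
from crestflow.bifurcation import test_fork as fork_interaction_test
from crestflow.synthetic import _logistic

from conftest import truth_fork_path


@pytest.fixture(scope="module")
def fork_data():
    emb, truth, expr = cf.default_dataset(n_cells=600, n_background=100, seed=3)
    norm = cf.normalize_log(expr)
    return truth, norm, truth_fork_path(truth)


class TestActivationTimingOracle:
    """Worked examples of the binned relative-expression-rate formula."""

    def test_linear_ramp_rate_two_ninths(self):
        # f(b) = (b-1)/9 over 10 bins: r = 2/9 at every interior bin
        grid = np.linspace(0, 1, 200)
        trend = grid  # linear; bin means hit (b + 0.5)/10-like uniform spacing
        res = activation_timing(trend, grid, fork_pseudotime=0.5, rate_threshold=0.3)
        np.testing.assert_allclose(res.rates, 2.0 / 9.0, atol=1e-3)
        assert res.label == "not-activated"  # 2/9 < 0.3

    def test_constant_trend_degenerate(self):
        grid = np.linspace(0, 1, 50)
        res = activation_timing(np.ones(50), grid, fork_pseudotime=0.5)
        assert res.degenerate and res.label == "not-activated" and res.bin is None

    def test_step_trend_activates_at_bin_five(self):
        # f = (0,0,0,0,0,1,1,1,1,1): r(bin5) = (f6 - f4)/1 = 1 > 0.3
        grid = np.linspace(0, 1, 100, endpoint=False) + 0.005
        trend = (grid >= 0.5).astype(float)
        res = activation_timing(trend, grid, fork_pseudotime=1.0, rate_threshold=0.3)
        np.testing.assert_allclose(
            res.bin_means, [0, 0, 0, 0, 0, 1, 1, 1, 1, 1], atol=1e-12
        )
        assert res.bin == 5
        assert res.rates[3] == pytest.approx(1.0)  # interior bin 5 (1-based)

    def test_rates_bounded_by_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            trend = rng.normal(size=100)
            res = activation_timing(trend, np.linspace(0, 1, 100), 0.5)
            assert np.all(np.abs(res.rates) <= 1.0 + 1e-12)


class TestForkTest:
    def test_branch_swap_leaves_p_unchanged(self, fork_data):
        truth, norm, path = fork_data
        genes = truth.genes
        sel = genes[genes.role == "noise"]["gene_id"].tolist()[:40]
        sub = norm.subset_genes(sel).to_frame()
        a = fork_interaction_test(sub, path)
        swapped = path.__class__(
            cell_indices=path.cell_indices,
            branch_labels=np.where(
                path.branch_labels == "branch-1", "branch-2",
                np.where(path.branch_labels == "branch-2", "branch-1",
                         path.branch_labels),
            ),
            pseudotime=path.pseudotime,
            fork_pseudotime=path.fork_pseudotime,
            fork_node=path.fork_node,
            source=path.source,
            targets=path.targets,
            node_labels=path.node_labels,
        )
        b = fork_interaction_test(sub, swapped)
        np.testing.assert_allclose(a.p.values, b.p.values, rtol=1e-8, atol=1e-12)

    def test_diverging_gene_detected(self, fork_data):
        truth, norm, path = fork_data
        early = truth.genes.query("role == 'early'")["gene_id"].tolist()
        res = fork_interaction_test(norm.subset_genes(early).to_frame(), path)
        assert (res.q < 0.1).mean() >= 0.95

    def test_single_branch_input_rejected(self, fork_data):
        truth, norm, path = fork_data
        single = path.__class__(
            cell_indices=path.cell_indices,
            branch_labels=np.full(len(path.cell_indices), "path"),
            pseudotime=path.pseudotime,
            fork_pseudotime=None, fork_node=None,
            source=0, targets=(1,), node_labels={},
        )
        with pytest.raises(ValueError, match="test_association"):
            fork_interaction_test(norm.values[:3], single)


class TestBranchAssignment:
    def test_planted_genes_assigned_to_their_branch(self, fork_data):
        truth, norm, path = fork_data
        report = cf.analyze_fork(norm.to_frame(), path)
        merged = report.merge(
            truth.genes.rename(columns={"branch": "true_branch"}),
            left_on="gene", right_on="gene_id",
        )
        planted = merged[merged.role.isin(["early", "late"])]
        correct = (
            ((planted.branch == "branch-1") & (planted.true_branch == "glial"))
            | ((planted.branch == "branch-2")
               & (planted.true_branch == "sympathoadrenal"))
        )
        assigned = planted.branch.apply(lambda b: isinstance(b, str))
        assert assigned.mean() >= 0.9
        assert correct[assigned].mean() >= 0.95

    def test_decreasing_gene_unassigned(self, fork_data):
        truth, norm, path = fork_data
        # NC markers fall on both branches: slope > 0 fails everywhere
        nc = truth.genes.query("module_id == 'marker_NC'")["gene_id"].tolist()
        stats = fork_interaction_test(norm.subset_genes(nc).to_frame(), path)
        assign = cf.assign_branch_specific(
            stats, norm.subset_genes(nc).to_frame(), path
        )
        assert assign["branch"].isna().all()

    def test_effect_cutoff_above_signal_blocks_assignment(self, fork_data):
        truth, norm, path = fork_data
        early = truth.genes.query("module_id == 'early_glial'")["gene_id"].tolist()[:5]
        sub = norm.subset_genes(early).to_frame()
        stats = fork_interaction_test(sub, path)
        assign = cf.assign_branch_specific(stats, sub, path, effect_cutoff=50.0)
        assert assign["branch"].isna().all()

    def test_early_late_timing_labels(self, fork_data):
        truth, norm, path = fork_data
        report = cf.analyze_fork(norm.to_frame(), path)
        merged = report.merge(truth.genes, left_on="gene", right_on="gene_id")
        planted = merged[merged.role.isin(["early", "late"])]
        ok = (
            ((planted.role == "early") & (planted.timing == "early"))
            | ((planted.role == "late") & (planted.timing == "late"))
        )
        assert ok.mean() >= 0.8


class TestNullCalibration:
    def test_identical_curve_genes_rarely_flagged(self):
        # same mean curve on both branches, noise only: <= 5% flagged at 0.1
        rng = np.random.default_rng(7)
        n_inst, flagged, total = 30, 0, 0
        for _ in range(n_inst):
            n = 200
            t = np.sort(rng.uniform(0, 2, n))
            lab = np.where(t <= 1.0, "pre-fork",
                           np.where(rng.random(n) < 0.5, "branch-1", "branch-2"))
            base = _logistic((t - 1.0) / 0.2)
            Y = base[None, :] + rng.normal(0, 0.3, size=(20, n))
            path = truth_path(t, lab)
            res = fork_interaction_test(Y, path, fdr_cut=0.1)
            flagged += int(res.candidate.sum())
            total += 20
        assert flagged / total <= 0.05


def truth_path(t, lab):
    from crestflow.tree import ForkPath

    return ForkPath(
        cell_indices=np.arange(len(t)), branch_labels=lab, pseudotime=t,
        fork_pseudotime=1.0, fork_node=None, source=0, targets=(1, 2),
        node_labels={},
    )
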