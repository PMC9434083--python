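"""Generator contracts: geometry, allocation, closed-form means, reproducibility."""

import numpy as np
import pandas as pd
import pytest

import crestflow as cf
from crestflow.synthetic import (
    ModuleSpec,
    Segment,
    TopologySpec,
    default_modules,
    module_mean,
    simulate_expression,
    simulate_trajectory,
    y_topology,
)


class TestTopology:
    def test_rejects_two_roots(self):
        with pytest.raises(ValueError, match="root"):
            TopologySpec(
                [Segment("a", None, 1.0, (1, 0)), Segment("b", None, 1.0, (0, 1))],
                {"a": 0.5, "b": 0.5},
            )

    def test_rejects_zero_length(self):
        with pytest.raises(ValueError, match="length"):
            TopologySpec([Segment("a", None, 0.0, (1, 0))], {"a": 1.0})

    def test_rejects_inconsistent_dims(self):
        with pytest.raises(ValueError, match="dimension"):
            TopologySpec(
                [Segment("a", None, 1.0, (1, 0)), Segment("b", "a", 1.0, (1, 0, 0))],
                {"a": 0.5, "b": 0.5},
            )

    def test_fork_pseudotime(self):
        assert y_topology().fork_pseudotimes() == {"NC": 1.0}


class TestTrajectory:
    def test_zero_noise_cells_lie_on_segments(self):
        topo = y_topology()
        emb, truth = simulate_trajectory(topo, 300, 0.0, seed=0)
        for seg in topo.segments:
            m = truth.segment == seg.id
            start = topo.start_position(seg.id)
            d = np.asarray(seg.direction) / np.linalg.norm(seg.direction)
            u = truth.pseudotime[m] - topo.t_start(seg.id)
            expected = start[None, :] + u[:, None] * d[None, :]
            np.testing.assert_allclose(emb[m], expected, atol=1e-12)

    def test_allocation_exact(self):
        topo = y_topology(fractions=(0.5, 0.25, 0.25))
        _, truth = simulate_trajectory(topo, 400, 0.0, seed=1)
        counts = pd.Series(truth.segment).value_counts()
        assert counts["NC"] == 200 and counts["glial"] == 100
        assert counts["sympathoadrenal"] == 100

    def test_same_seed_bit_identical(self):
        a = simulate_trajectory(y_topology(), 200, 0.05, seed=42)
        b = simulate_trajectory(y_topology(), 200, 0.05, seed=42)
        np.testing.assert_array_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1].cells, b[1].cells)


class TestExpression:
    def test_zero_amplitude_constant_mean(self):
        topo = y_topology()
        m = ModuleSpec("flat", "early", "glial", 5.0, 0.0, 0.5, 0.1, 1, repression=1.2)
        t = np.linspace(0, 2, 50)
        seg = np.array(["NC"] * 25 + ["glial"] * 25)
        mu = module_mean(m, t, seg, topo)
        np.testing.assert_allclose(mu, 5.0)

    def test_logistic_limit_far_before_activation(self):
        topo = y_topology()
        m = ModuleSpec("e", "early", "glial", 10.0, 100.0, 0.6, 0.05, 1, repression=1.2)
        mu = module_mean(m, np.array([0.05]), np.array(["NC"]), topo)
        assert abs(mu[0] - 10.0) < 0.01 * 10.0

    def test_monte_carlo_mean_matches_closed_form(self):
        # many cells frozen at one pseudotime: empirical mean ~ mu within 3 SE
        topo = y_topology()
        mod = ModuleSpec("e", "early", "glial", 20.0, 100.0, 0.6, 0.08, 1, repression=1.15)
        n = 2000
        cells = pd.DataFrame(
            {"cell_id": [f"c{i}" for i in range(n)],
             "pseudotime": 0.7, "segment": "NC"}
        )
        truth = cf.SyntheticTruth(cells=cells, topology=topo, fork_pseudotime=1.0)
        disp = 5.0
        expr = simulate_expression(
            truth, [mod], nb_dispersion=disp,
            lib_size_lognormal_params=(0.0, 0.0), seed=3,
        )
        mu = module_mean(mod, np.array([0.7]), np.array(["NC"]), topo)[0]
        counts = expr.values[0].astype(float)
        se = np.sqrt((mu + mu**2 / disp) / n)
        assert abs(counts.mean() - mu) < 3 * se

    def test_truth_slope_sign_recovery(self, small_dataset):
        # regressing log expression on true pseudotime within the target branch
        # recovers a positive slope for >=95% of activating genes
        _, truth, expr = small_dataset
        norm = cf.normalize_log(expr)
        clean = ~truth.cells["low_quality"].to_numpy()
        vals = norm.values[:, clean] if norm.n_cells == len(clean) else norm.values
        t = truth.cells.loc[clean, "pseudotime"].to_numpy()
        seg = truth.cells.loc[clean, "segment"].to_numpy()
        genes = truth.genes.set_index("gene_id")
        ok = total = 0
        gene_pos = {g: i for i, g in enumerate(norm.gene_ids)}
        for g, row in genes[genes.role.isin(["early", "late"])].iterrows():
            path = {"NC", row.branch}
            m = np.isin(seg, list(path))
            y = vals[gene_pos[g]][m]
            slope = np.polyfit(t[m], y, 1)[0]
            ok += slope > 0
            total += 1
        assert ok / total >= 0.95

    def test_low_quality_cells_fail_qc(self, small_dataset):
        _, truth, expr = small_dataset
        kept, _ = cf.filter_cells(expr)
        lowq = set(truth.cells.loc[truth.cells["low_quality"], "cell_id"])
        assert not lowq & set(kept)

    def test_ercc_fraction_in_range(self, small_dataset):
        _, truth, expr = small_dataset
        clean = ~truth.cells["low_quality"].to_numpy()
        ercc = expr.values[expr.ercc_mask][:, clean].sum(axis=0)
        total = expr.values[:, clean].sum(axis=0)
        frac = ercc / total
        assert frac.min() >= 0.02 and frac.max() <= 0.08

    def test_same_seed_reproducible(self):
        topo = y_topology()
        out = []
        for _ in range(2):
            _, truth = simulate_trajectory(topo, 100, 0.05, seed=9)
            expr = simulate_expression(truth, default_modules(topo, n_background=50), seed=10)
            out.append(expr.values)
        np.testing.assert_array_equal(out[0], out[1])

    def test_activation_outside_range_rejected(self):
        topo = y_topology()
        _, truth = simulate_trajectory(topo, 50, 0.0, seed=0)
        bad = ModuleSpec("b", "neutral", None, 1.0, 1.0, 5.0, 0.1, 2)
        with pytest.raises(ValueError, match="activation"):
            simulate_expression(truth, [bad], seed=0)


class TestRegulonActivity:
    def test_scores_clipped_to_unit_interval(self, y_data):
        _, truth = y_data
        act = cf.simulate_regulon_activity(truth, 10, 2, noise_sd=0.5, seed=0)
        v = act.scores.to_numpy()
        assert v.min() >= 0.0 and v.max() <= 1.0

    def test_zero_noise_within_cluster_correlation_one(self, y_data):
        _, truth = y_data
        act = cf.simulate_regulon_activity(truth, 10, 5, noise_sd=0.0, seed=0)
        labels = truth.regulon_clusters
        v = act.scores.to_numpy()
        for c in range(5):
            members = np.flatnonzero(labels.to_numpy() == c)
            corr = np.corrcoef(v[members])
            np.testing.assert_allclose(corr, 1.0, atol=1e-12)

    def test_within_beats_between_cluster_correlation(self, y_data):
        _, truth = y_data
        act = cf.simulate_regulon_activity(truth, 30, 5, noise_sd=0.05, seed=1)
        labels = truth.regulon_clusters.to_numpy()
        corr = np.corrcoef(act.scores.to_numpy())
        same = labels[:, None] == labels[None, :]
        iu = np.triu_indices(len(labels), k=1)
        within = corr[iu][same[iu]].mean()
        between = corr[iu][~same[iu]].mean()
        assert within > between

    def test_reproducible(self, y_data):
        _, truth = y_data
        a = cf.simulate_regulon_activity(truth, 8, 2, seed=3)
        b = cf.simulate_regulon_activity(truth, 8, 2, seed=3)
        pd.testing.assert_frame_equal(a.scores, b.scores)
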