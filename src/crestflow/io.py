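"""File formats, run configuration and the end-to-end pipeline driver.

Matrices travel as Matrix Market sparse triplets (``matrix.mtx`` with
``genes.tsv`` / ``cells.tsv`` sidecars) or as dense TSV; embeddings,
pseudotime, reports and trends are TSV with headers; marker sets are JSON
(``{"type": ["gene", ...]}``). All indices are 0-based in memory and 1-based
on disk in the Matrix Market convention. Every pipeline run writes a manifest
recording the package version, the seed, every parameter, and a sha256
checksum per output so reruns can be compared bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .qc import ExpressionMatrix

logger = logging.getLogger("crestflow")

__all__ = [
    "write_expression",
    "read_expression",
    "write_dense",
    "read_dense",
    "write_marker_sets",
    "read_marker_sets",
    "load_dataset",
    "RunConfig",
    "run_pipeline",
]


# ---------------------------------------------------------------- formats

def write_expression(matrix: ExpressionMatrix, outdir) -> None:
    """Write matrix.mtx + genes.tsv/cells.tsv under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    m = sp.coo_matrix(matrix.values)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), m)
    pd.DataFrame(
        {"gene_id": matrix.gene_ids, "is_ercc": matrix.ercc_mask.astype(int)}
    ).to_csv(outdir / "genes.tsv", sep="\t", index=False)
    pd.DataFrame({"cell_id": matrix.cell_ids}).to_csv(
        outdir / "cells.tsv", sep="\t", index=False
    )


def read_expression(
    path, layer: str = "counts", ercc_prefix: str = "ERCC-"
) -> ExpressionMatrix:
    """Read matrix.mtx + sidecars written by :func:`write_expression`."""
    path = Path(path)
    mtx = path / "matrix.mtx"
    if not mtx.exists():
        raise FileNotFoundError(f"missing {mtx}")
    values = np.asarray(scipy.io.mmread(str(mtx)).todense())
    genes = pd.read_csv(path / "genes.tsv", sep="\t")
    cells = pd.read_csv(path / "cells.tsv", sep="\t")
    gene_ids = genes["gene_id"].astype(str).tolist()
    cell_ids = cells["cell_id"].astype(str).tolist()
    if len(set(cell_ids)) != len(cell_ids):
        raise ValueError(f"{path / 'cells.tsv'} contains duplicate cell ids")
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError(f"{path / 'genes.tsv'} contains duplicate gene ids")
    if values.shape != (len(gene_ids), len(cell_ids)):
        raise ValueError(
            f"matrix shape {values.shape} does not match sidecars "
            f"({len(gene_ids)} genes, {len(cell_ids)} cells) in {path}"
        )
    if "is_ercc" in genes.columns:
        ercc = genes["is_ercc"].astype(bool).to_numpy()
    else:
        ercc = np.array([g.startswith(ercc_prefix) for g in gene_ids])
    if layer == "counts":
        values = values.astype(np.int64)
    return ExpressionMatrix(values, gene_ids, cell_ids, ercc, layer=layer)


def write_dense(matrix: ExpressionMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t")


def read_dense(path, layer: str = "counts", ercc_prefix: str = "ERCC-") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    gene_ids = df.index.astype(str).tolist()
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError(f"{path} contains duplicate gene ids")
    values = df.to_numpy()
    if layer == "counts":
        values = values.astype(np.int64)
    return ExpressionMatrix(
        values,
        gene_ids,
        df.columns.astype(str).tolist(),
        np.array([g.startswith(ercc_prefix) for g in gene_ids]),
        layer=layer,
    )


def write_marker_sets(marker_sets: dict[str, list[str]], path) -> None:
    Path(path).write_text(json.dumps(marker_sets, indent=2, sort_keys=True))


def read_marker_sets(path) -> dict[str, list[str]]:
    data = json.loads(Path(path).read_text())
    if not isinstance(data, dict) or not all(
        isinstance(v, list) for v in data.values()
    ):
        raise ValueError(f"{path} is not a {{type: [genes]}} mapping")
    return {str(k): [str(g) for g in v] for k, v in data.items()}


def load_dataset(path, ercc_prefix: str = "ERCC-") -> dict:
    """Load a dataset directory: expression plus optional sidecar inputs.

    Recognized members: ``matrix.mtx``+sidecars or ``matrix.tsv``;
    ``embedding.tsv`` (cells x dims); ``regulon_activity.tsv`` and
    ``tf_expression.tsv``; ``markers.json``; ``truth_cells.tsv``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    out: dict = {}
    if (path / "matrix.mtx").exists():
        out["expression"] = read_expression(path, ercc_prefix=ercc_prefix)
    elif (path / "matrix.tsv").exists():
        out["expression"] = read_dense(path / "matrix.tsv", ercc_prefix=ercc_prefix)
    else:
        raise FileNotFoundError(f"no matrix.mtx or matrix.tsv under {path}")
    emb = path / "embedding.tsv"
    if emb.exists():
        df = pd.read_csv(emb, sep="\t", index_col=0)
        expr = out["expression"]
        if list(df.index.astype(str)) != list(expr.cell_ids):
            common = [c for c in expr.cell_ids if c in set(df.index.astype(str))]
            if len(common) != len(df):
                raise ValueError(
                    f"embedding covers {len(df)} cells but the matrix has "
                    f"{expr.n_cells}; ids do not line up"
                )
            df = df.loc[common]
        out["embedding"] = df
    for name, key in (("regulon_activity.tsv", "regulon_activity"),
                      ("tf_expression.tsv", "tf_expression")):
        f = path / name
        if f.exists():
            out[key] = pd.read_csv(f, sep="\t", index_col=0)
    mk = path / "markers.json"
    if mk.exists():
        out["marker_sets"] = read_marker_sets(mk)
    tc = path / "truth_cells.tsv"
    if tc.exists():
        out["truth_cells"] = pd.read_csv(tc, sep="\t")
    return out


# ---------------------------------------------------------------- config

@dataclass
class RunConfig:
    """Flat parameter schema for the pipeline; unknown keys are rejected."""

    seed: int = 0
    # simulation
    n_cells: int = 500
    embedding_noise_sd: float = 0.05
    n_low_quality_cells: int = 30
    n_background_genes: int = 1000
    # qc / preprocessing
    min_transcripts: float = 5e4
    max_transcripts: float = 6e6
    min_genes: int = 1000
    max_genes: int = 10000
    max_ercc_fraction: float = 0.15
    target_sum: float = 1e6
    n_overdispersed: int = 500
    knn_neighbors: int = 15
    smooth_steps: int = 3
    # tree
    n_nodes: int = 30
    sigma: float | None = None
    lambda_: float = 1.0
    tree_max_iter: int = 300
    tree_tol: float = 1e-4
    pseudotime_mode: str = "soft"
    # association
    spline_df: int = 5
    fdr_threshold: float = 1e-4
    a_cut: float = 0.025
    # fork
    fork_fdr_cut: float = 0.1
    upreg_fdr: float = 0.05
    effect_cutoff: float = 0.2
    n_bins: int = 10
    rate_threshold: float = 0.1
    # module correlations
    window_size: int | None = None
    window_step: int | None = None
    # regulons
    n_regulons: int = 30
    n_regulon_clusters: int = 5
    regulon_noise_sd: float = 0.05
    regulon_a_cut: float = 0.02
    metaregulon_neighbors: int = 40
    metaregulon_resolution: float = 1.0
    summary_bins: int = 20
    run_regulons: bool = True
    # annotation / hub
    annotation_threshold: float = 0.6
    cell_cluster_neighbors: int = 10
    cell_cluster_resolution: float = 4.0
    hub_fraction_cutoff: float = 0.8

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------- pipeline

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run simulate -> qc -> tree -> association -> fork -> correlations ->
    regulons -> hub on the default synthetic preset; write all stage outputs
    plus a manifest with parameters and per-file checksums.

    Returns the manifest dictionary. Reruns with an identical config are
    bit-identical (all randomness derives from ``config.seed``).
    """
    from . import __version__
    from . import annotation as ann
    from . import association as assoc
    from . import bifurcation as bif
    from . import modcorr
    from . import qc as qcmod
    from . import regulons as reg
    from . import synthetic as syn
    from . import tree as treemod

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config
    stages: dict[str, str] = {}
    seed = int(cfg.seed)

    # --- simulate
    topo = syn.y_topology()
    embedding, truth = syn.simulate_trajectory(
        topo, cfg.n_cells, cfg.embedding_noise_sd, seed=seed
    )
    modules = syn.default_modules(topo, n_background=cfg.n_background_genes)
    expr = syn.simulate_expression(
        truth, modules, n_low_quality_cells=cfg.n_low_quality_cells, seed=seed + 1
    )
    write_expression(expr, outdir / "simulated")
    pd.DataFrame(embedding, index=truth.cells.loc[~truth.cells["low_quality"], "cell_id"]).to_csv(
        outdir / "embedding.tsv", sep="\t"
    )
    truth.cells.to_csv(outdir / "truth_cells.tsv", sep="\t", index=False)
    stages["simulate"] = "ok"

    # --- qc
    kept, report = qcmod.filter_cells(
        expr,
        qcmod.QCThresholds(
            cfg.min_transcripts, cfg.max_transcripts, cfg.min_genes,
            cfg.max_genes, cfg.max_ercc_fraction,
        ),
    )
    report.to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
    expr_f = expr.subset_cells(kept)
    clean_ids = truth.cells.loc[~truth.cells["low_quality"], "cell_id"].tolist()
    keep_clean = [c for c in kept if c in set(clean_ids)]
    expr_f = expr_f.subset_cells(keep_clean)
    pos = {c: i for i, c in enumerate(clean_ids)}
    emb_f = embedding[[pos[c] for c in keep_clean]]
    cell_sel = truth.cells.set_index("cell_id").loc[keep_clean]
    norm = qcmod.normalize_log(expr_f, target_sum=cfg.target_sum)
    od = qcmod.select_overdispersed(norm, n_top=cfg.n_overdispersed)
    od.to_csv(outdir / "overdispersed.tsv", sep="\t", index=False)
    graph = qcmod.build_knn_graph(emb_f, n_neighbors=cfg.knn_neighbors)
    imputed = qcmod.knn_smooth(norm, graph, steps=cfg.smooth_steps)
    stages["qc"] = "ok"

    # --- tree + pseudotime
    ptree = treemod.fit_principal_tree(
        emb_f, n_nodes=cfg.n_nodes, sigma=cfg.sigma, lambda_=cfg.lambda_,
        max_iter=cfg.tree_max_iter, tol=cfg.tree_tol, seed=seed + 2,
    )
    root_scores = -cell_sel["pseudotime"].to_numpy()  # earliest cells score highest
    root = treemod.select_root(ptree, root_scores)
    pt = treemod.compute_pseudotime(ptree, root, mode=cfg.pseudotime_mode)
    milestones, ms_assign = treemod.identify_milestones(ptree, pt)
    pd.DataFrame(
        {
            "cell_id": keep_clean,
            "pseudotime": pt.cell_pseudotime,
            "segment": pt.cell_segment,
            "milestone": ms_assign,
        }
    ).to_csv(outdir / "pseudotime.tsv", sep="\t", index=False)
    stages["tree"] = "ok"

    # --- association on overdispersed genes
    od_genes = od["gene_id"].tolist()
    sub = norm.subset_genes(od_genes)
    res = assoc.test_association(
        sub.to_frame(), pt, spline_df=cfg.spline_df,
        fdr_threshold=cfg.fdr_threshold, a_cut=cfg.a_cut,
    )
    res.table.to_csv(outdir / "association.tsv", sep="\t", index=False)
    stages["association"] = "ok"

    # --- fork analysis between the two tips reached from the root
    tips = [m.node for m in milestones if m.kind == "tip" and m.node != root]
    tip_t = {n: pt.node_pseudotime[n] for n in tips}
    far = sorted(tips, key=lambda n: -tip_t[n])[:2]
    fork_report = None
    if len(far) == 2:
        path = treemod.extract_path(ptree, pt, root, far)
        fork_report = bif.analyze_fork(
            norm.to_frame(), path, spline_df=cfg.spline_df,
            fdr_cut=cfg.fork_fdr_cut, upreg_fdr=cfg.upreg_fdr,
            effect_cutoff=cfg.effect_cutoff, n_bins=cfg.n_bins,
            rate_threshold=cfg.rate_threshold,
        )
        fork_report.to_csv(outdir / "fork_report.tsv", sep="\t", index=False)
        stages["fork"] = "ok"

        # --- module correlations using the called early genes per branch
        ea = fork_report.query("branch == 'branch-1' and timing == 'early'")["gene"]
        eb = fork_report.query("branch == 'branch-2' and timing == 'early'")["gene"]
        if len(ea) >= 2 and len(eb) >= 2:
            wsize = cfg.window_size or max(30, len(keep_clean) // 20)
            step = cfg.window_step or max(wsize // 3, 1)
            win = modcorr.make_windows(
                pt.cell_pseudotime[path.cell_indices], window_size=min(wsize, len(path.cell_indices)),
                step=step, scheme="sliding",
            )
            summary, _ = modcorr.window_module_correlations(
                norm.values[:, path.cell_indices], norm.gene_ids, win,
                modcorr.GeneModule("early_b1", tuple(ea), "branch-1"),
                modcorr.GeneModule("early_b2", tuple(eb), "branch-2"),
            )
            summary.to_csv(outdir / "module_correlations.tsv", sep="\t", index=False)
            stages["module_correlations"] = "ok"
        else:
            stages["module_correlations"] = "skipped (too few early genes)"
    else:
        stages["fork"] = "skipped (no two tips)"

    # --- regulons
    if cfg.run_regulons:
        act = syn.simulate_regulon_activity(
            truth, n_regulons=cfg.n_regulons, n_clusters=cfg.n_regulon_clusters,
            noise_sd=cfg.regulon_noise_sd, seed=seed + 3,
        )
        act = reg.weight_auc_by_tf(act)
        scores = act.scores[keep_clean]
        rres = assoc.test_association(
            scores, pt, spline_df=cfg.spline_df,
            fdr_threshold=cfg.fdr_threshold, a_cut=cfg.regulon_a_cut,
        )
        sig = rres.significant_features() or list(scores.index)
        trends = assoc.fit_trends(scores.loc[sig], pt, spline_df=cfg.spline_df)
        flat = np.column_stack([trends.values[s] for s in trends.segments])
        grid_all = np.concatenate([trends.grid[s] for s in trends.segments])
        clustering = reg.cluster_metaregulons(
            pd.DataFrame(flat, index=sig),
            n_neighbors=cfg.metaregulon_neighbors,
            resolution=cfg.metaregulon_resolution,
            seed=seed + 4,
            grid_t=grid_all,
        )
        clustering.labels.rename("cluster").to_frame().assign(
            tf=[act.tf_map[r] for r in clustering.labels.index]
        ).to_csv(outdir / "metaregulons.tsv", sep="\t")
        bins = reg.bin_summaries(
            scores, pt.cell_pseudotime, n_bins=cfg.summary_bins
        )
        bins.to_csv(outdir / "regulon_bins.tsv", sep="\t")
        stages["regulons"] = "ok"
    else:
        stages["regulons"] = "skipped (disabled)"

    # --- annotation + hub
    truth_genes = truth.genes
    marker_sets = {
        "NC": truth_genes.query("module_id == 'marker_NC'")["gene_id"].tolist(),
        "glial": truth_genes.query("module_id == 'marker_glial'")["gene_id"].tolist(),
        "sympathoadrenal": truth_genes.query(
            "module_id == 'marker_sympathoadrenal'"
        )["gene_id"].tolist(),
    }
    marker_sets = {k: v for k, v in marker_sets.items() if v}
    if marker_sets:
        annotated = ann.score_cell_types(
            imputed, marker_sets, thresholds=cfg.annotation_threshold
        )
        comms = ann.cluster_cells(
            emb_f, n_neighbors=cfg.cell_cluster_neighbors,
            resolution=cfg.cell_cluster_resolution, seed=seed + 5,
        )
        hub = ann.detect_hub(annotated, comms, fraction_cutoff=cfg.hub_fraction_cutoff)
        pd.DataFrame(
            {
                "cell_id": keep_clean,
                "label": annotated.labels,
                "reason": annotated.reasons,
                "community": comms,
                "is_hub": hub.hub_mask,
            }
        ).to_csv(outdir / "annotation.tsv", sep="\t", index=False)
        hub.cluster_table.to_csv(outdir / "hub_clusters.tsv", sep="\t", index=False)
        if hub.hub_mask.sum() >= 3 and (~hub.hub_mask).sum() >= 3:
            markers = ann.hub_markers(norm, hub.hub_mask)
            markers.to_csv(outdir / "hub_markers.tsv", sep="\t", index=False)
        stages["hub"] = "ok"
    else:
        stages["hub"] = "skipped (no marker modules)"

    checksums = {
        p.name: _sha256(p) for p in sorted(outdir.rglob("*")) if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "version": __version__,
        "seed": seed,
        "parameters": cfg.to_dict(),
        "stages": stages,
        "checksums": checksums,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
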