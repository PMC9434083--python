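"""Marker-based cell-type scoring and "hub"-state detection.

Cells are scored per cell type as the mean of per-gene min-max-scaled imputed
expression over that type's marker genes. A cell is labelled with the unique
type whose score clears its threshold; cells passing zero or two-plus
thresholds stay unassigned (with the reason recorded). The transcriptionally
uncommitted "hub" state is then called at the community level: every Leiden
community of the cell kNN graph whose unassigned fraction reaches the cutoff
(inclusive, default 80%) is flagged, and hub cells are the members of flagged
communities. Hub markers come from a two-sided Wilcoxon rank-sum test of hub
versus all other cells.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .qc import ExpressionMatrix
from .regulons import leiden_cluster_graph

logger = logging.getLogger("crestflow")

__all__ = [
    "CellAnnotation",
    "HubCallResult",
    "score_cell_types",
    "cluster_cells",
    "detect_hub",
    "hub_markers",
]


@dataclass
class CellAnnotation:
    scores: pd.DataFrame  # cells x types
    thresholds: dict[str, float]
    labels: np.ndarray  # type name or 'unassigned'
    reasons: np.ndarray  # '' | 'no-type' | 'multi-type'

    @property
    def unassigned(self) -> np.ndarray:
        return self.labels == "unassigned"


@dataclass
class HubCallResult:
    cluster_table: pd.DataFrame  # cluster, n_cells, unassigned_fraction, is_hub
    hub_clusters: list[int]
    hub_mask: np.ndarray
    fraction_cutoff: float
    markers: pd.DataFrame | None = None


def score_cell_types(
    imputed: ExpressionMatrix,
    marker_sets: dict[str, list[str]],
    thresholds: dict[str, float] | float = 0.5,
    scaling: str = "minmax",
) -> CellAnnotation:
    """Score and label cells from marker gene sets.

    ``scaling='minmax'`` rescales each marker gene to [0, 1] across cells
    before averaging (``'zscore'`` standardizes instead). Markers absent from
    the matrix are dropped with a warning; a type whose markers are all absent
    is a configuration error.
    """
    if scaling not in ("minmax", "zscore"):
        raise ValueError("scaling must be 'minmax' or 'zscore'")
    if not marker_sets:
        raise ValueError("marker_sets is empty")
    if isinstance(thresholds, (int, float)):
        thresholds = {t: float(thresholds) for t in marker_sets}
    vals = imputed.values
    gene_pos = {g: i for i, g in enumerate(imputed.gene_ids)}
    scores = {}
    for ctype, markers in marker_sets.items():
        if not markers:
            raise ValueError(f"marker set for {ctype!r} is empty")
        present = [g for g in markers if g in gene_pos]
        absent = sorted(set(markers) - set(present))
        if absent:
            warnings.warn(f"{ctype}: {len(absent)} markers absent and dropped")
        if not present:
            raise ValueError(f"no marker of type {ctype!r} is present in the matrix")
        rows = vals[[gene_pos[g] for g in present], :]
        if scaling == "minmax":
            lo = rows.min(axis=1, keepdims=True)
            rng = rows.max(axis=1, keepdims=True) - lo
            scaled = np.where(rng > 0, (rows - lo) / np.where(rng > 0, rng, 1.0), 0.0)
        else:
            mu = rows.mean(axis=1, keepdims=True)
            sd = rows.std(axis=1, keepdims=True)
            scaled = np.where(sd > 0, (rows - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        scores[ctype] = scaled.mean(axis=0)
    score_df = pd.DataFrame(scores, index=imputed.cell_ids)
    passing = score_df.gt(pd.Series(thresholds))
    n_pass = passing.sum(axis=1).to_numpy()
    labels = np.full(imputed.n_cells, "unassigned", dtype=object)
    reasons = np.full(imputed.n_cells, "", dtype=object)
    single = n_pass == 1
    pass_arr = passing.to_numpy()
    for i in np.flatnonzero(single):
        labels[i] = score_df.columns[pass_arr[i].argmax()]
    reasons[n_pass == 0] = "no-type"
    reasons[n_pass >= 2] = "multi-type"
    return CellAnnotation(
        scores=score_df,
        thresholds=dict(thresholds),
        labels=labels.astype(str),
        reasons=reasons.astype(str),
    )


def cluster_cells(
    embedding: np.ndarray,
    n_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Seeded Leiden communities on the euclidean kNN graph of the embedding."""
    from sklearn.neighbors import NearestNeighbors

    X = np.asarray(embedding, float)
    nn = NearestNeighbors(n_neighbors=min(n_neighbors, len(X) - 1) + 1).fit(X)
    dist, idx = nn.kneighbors(X)
    return leiden_cluster_graph(
        dist[:, 1:], idx[:, 1:], n_items=len(X), resolution=resolution, seed=seed
    )


def detect_hub(
    annotation,
    communities: np.ndarray,
    fraction_cutoff: float = 0.8,
) -> HubCallResult:
    """Flag communities whose unassigned fraction reaches the cutoff.

    ``annotation`` is a :class:`CellAnnotation` or a boolean per-cell
    unassigned mask. The comparison is inclusive (a community at exactly the
    cutoff is a hub community). No flagged community is a valid, empty result.
    """
    unassigned = (
        annotation.unassigned
        if isinstance(annotation, CellAnnotation)
        else np.asarray(annotation, dtype=bool)
    )
    communities = np.asarray(communities)
    if len(communities) != len(unassigned):
        raise ValueError("communities and annotation cover different cell counts")
    rows = []
    hub_clusters = []
    for c in sorted(set(communities.tolist())):
        m = communities == c
        frac = float(unassigned[m].mean())
        is_hub = frac >= fraction_cutoff
        if is_hub:
            hub_clusters.append(c)
        rows.append(
            {"cluster": c, "n_cells": int(m.sum()), "unassigned_fraction": frac, "is_hub": is_hub}
        )
    hub_mask = np.isin(communities, hub_clusters)
    return HubCallResult(
        cluster_table=pd.DataFrame(rows),
        hub_clusters=hub_clusters,
        hub_mask=hub_mask,
        fraction_cutoff=fraction_cutoff,
    )


def hub_markers(
    matrix: ExpressionMatrix, hub_mask: np.ndarray, fdr: float = 0.05
) -> pd.DataFrame:
    """Wilcoxon rank-sum markers of hub cells versus the rest.

    Effects are mean differences (hub minus rest) on the supplied layer
    (normalized/log recommended); the table is ranked hub-elevated genes
    first, by q-value within each direction.
    """
    hub_mask = np.asarray(hub_mask, dtype=bool)
    n_hub = int(hub_mask.sum())
    n_rest = int((~hub_mask).sum())
    if n_hub < 3 or n_rest < 3:
        raise ValueError("both groups need at least 3 cells")
    A = matrix.values[:, hub_mask]
    B = matrix.values[:, ~hub_mask]
    stat, p = stats.ranksums(A, B, axis=1)
    p = np.where(np.isfinite(p), p, 1.0)
    effect = A.mean(axis=1) - B.mean(axis=1)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    table = pd.DataFrame(
        {
            "gene": matrix.gene_ids,
            "effect": effect,
            "statistic": stat,
            "p": p,
            "q": q,
            "significant": q < fdr,
        }
    )
    table["_dir"] = np.where(table["effect"] > 0, 0, 1)
    table = (
        table.sort_values(["_dir", "q", "gene"], kind="mergesort")
        .drop(columns="_dir")
        .reset_index(drop=True)
    )
    return table
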