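"""Regulon-activity dynamics: TF weighting, metaregulon clustering, binning.

Regulon activity is consumed as an AUC-style per-cell recovery score in
[0, 1] (its inference is upstream of this package). Scores are optionally
weighted by the expression of the regulon's transcription factor: the weight
is the TF's log10 expression clamped to [0, 1] (so a TF with log10 expression
above 1 leaves the score untouched and an undetected TF silences it), and the
weighted score is weight times raw score.

Fitted activity trends over pseudotime are z-scored per regulon and clustered
by Leiden community detection on a cosine-distance kNN graph; each cluster is
a *metaregulon* whose trend is the plain mean of its members' trends.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger("crestflow")

__all__ = [
    "RegulonActivity",
    "MetaregulonClustering",
    "weight_auc_by_tf",
    "cluster_metaregulons",
    "bin_summaries",
    "leiden_cluster_graph",
]


@dataclass
class RegulonActivity:
    """Regulon x cell activity scores with the TF expression used to weight."""

    scores: pd.DataFrame  # regulons x cells, values in [0, 1]
    tf_map: dict[str, str]  # regulon -> TF
    tf_expression: pd.DataFrame  # TFs x cells, log10 scale
    weighted: bool = False

    def __post_init__(self) -> None:
        v = self.scores.to_numpy()
        if v.size and (np.nanmin(v) < -1e-9 or np.nanmax(v) > 1 + 1e-9):
            raise ValueError("regulon scores must lie in [0, 1]")

    @property
    def regulons(self) -> list[str]:
        return list(self.scores.index)

    @property
    def cells(self) -> list[str]:
        return list(self.scores.columns)


def weight_auc_by_tf(activity: RegulonActivity) -> RegulonActivity:
    """Clamp-and-multiply TF weighting of AUC scores.

    Per cell, ``w = clip(log10 TF expression, 0, 1)`` and the weighted score is
    ``w * score``. Weighting never increases a score and is idempotent once all
    weights are 1. Regulons whose TF is missing from the expression table pass
    through unweighted (logged).
    """
    out = activity.scores.copy()
    missing = []
    for reg in activity.regulons:
        tf = activity.tf_map.get(reg)
        if tf is None or tf not in activity.tf_expression.index:
            missing.append(reg)
            continue
        w = np.clip(
            activity.tf_expression.loc[tf, activity.scores.columns].to_numpy(float),
            0.0,
            1.0,
        )
        out.loc[reg] = activity.scores.loc[reg].to_numpy(float) * w
    if missing:
        logger.warning(
            "%d regulons had no TF expression and were left unweighted: %s",
            len(missing),
            missing[:5],
        )
    return replace(activity, scores=out, weighted=True)


@dataclass
class MetaregulonClustering:
    labels: pd.Series  # regulon -> cluster id (activation-ordered ints)
    metaregulon_trends: pd.DataFrame  # clusters x grid
    metric: str
    n_neighbors: int
    resolution: float


def _smooth_knn_weights(distances: np.ndarray) -> np.ndarray:
    """Locally-calibrated exponential kNN weights.

    Per item, weights are ``exp(-(d - rho)/sigma)`` with ``rho`` the nearest
    distance and ``sigma`` binary-searched so the weights sum to ``log2(k)``
    — the smooth-kNN calibration used by UMAP-style neighbor graphs. This
    keeps a handful of genuinely close neighbors at full weight and decays
    the rest, which is what lets modularity find fine structure even when the
    kNN graph is dense.
    """
    n, k = distances.shape
    target = np.log2(max(k, 2))
    W = np.zeros_like(distances, dtype=float)
    for i in range(n):
        d = distances[i]
        rho = d[0]
        lo, hi = 1e-12, 1e4
        for _ in range(64):
            mid = 0.5 * (lo + hi)
            if np.exp(-np.maximum(d - rho, 0.0) / mid).sum() > target:
                hi = mid
            else:
                lo = mid
        W[i] = np.exp(-np.maximum(d - rho, 0.0) / hi)
    return W


def leiden_cluster_graph(
    distances: np.ndarray,
    indices: np.ndarray,
    n_items: int,
    resolution: float,
    seed: int,
) -> np.ndarray:
    """Leiden partition of a kNN graph given neighbor indices and distances."""
    W = _smooth_knn_weights(np.asarray(distances, float))
    edges: dict[tuple[int, int], float] = {}
    for i in range(n_items):
        for w, j in zip(W[i], indices[i]):
            j = int(j)
            if i == j or w <= 1e-4:
                continue
            key = (min(i, j), max(i, j))
            edges[key] = max(edges.get(key, 0.0), float(w))
    g = ig.Graph(n=n_items, edges=list(edges.keys()))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=list(edges.values()),
        resolution_parameter=resolution,
        seed=seed,
    )
    return np.asarray(part.membership)


def cluster_metaregulons(
    trends: pd.DataFrame,
    n_neighbors: int = 40,
    resolution: float = 1.0,
    seed: int = 0,
    grid_t: np.ndarray | None = None,
) -> MetaregulonClustering:
    """Cluster fitted regulon trends into metaregulons.

    ``trends`` is regulons x grid of fitted activity. Trends are z-scored per
    regulon (so cosine distance ignores offset and positive scale) before the
    kNN graph is built; the partition comes from seeded Leiden community
    detection. Cluster ids are renumbered by the activation order of their
    metaregulon trend (center of mass along the grid), and each metaregulon
    trend is the unweighted mean of its members' *input* trends.
    """
    if len(trends) < 2:
        raise ValueError("need at least 2 regulon trends to cluster")
    X = trends.to_numpy(float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    flat = sd.ravel() <= 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant trends assigned to their own cluster")
    Z = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    n = len(trends)
    k = n_neighbors
    if k >= n:
        warnings.warn(f"n_neighbors={k} >= n_regulons={n}; reduced to {n - 1}")
        k = n - 1
    rows = np.flatnonzero(~flat)
    labels = np.full(n, -1, dtype=int)
    if rows.size >= 2:
        k_eff = min(k, rows.size - 1)
        nn = NearestNeighbors(n_neighbors=k_eff + 1, metric="cosine").fit(Z[rows])
        dist, idx = nn.kneighbors(Z[rows])
        labels[rows] = leiden_cluster_graph(
            dist[:, 1:], idx[:, 1:], n_items=rows.size, resolution=resolution, seed=seed
        )
    elif rows.size == 1:
        labels[rows[0]] = 0
    next_label = labels.max() + 1
    for r in np.flatnonzero(flat):
        labels[r] = next_label
        next_label += 1

    t = np.asarray(grid_t, float) if grid_t is not None else np.arange(X.shape[1], dtype=float)
    raw_ids = sorted(set(labels.tolist()))
    trends_by_cluster = {}
    order_key = {}
    for c in raw_ids:
        members = np.flatnonzero(labels == c)
        mtrend = X[members].mean(axis=0)
        trends_by_cluster[c] = mtrend
        w = mtrend - mtrend.min()
        order_key[c] = float((t * w).sum() / w.sum()) if w.sum() > 0 else float(t.mean())
    ordered = sorted(raw_ids, key=lambda c: (order_key[c], c))
    remap = {c: i for i, c in enumerate(ordered)}
    final = pd.Series([remap[c] for c in labels], index=trends.index, name="cluster")
    mt = pd.DataFrame(
        [trends_by_cluster[c] for c in ordered],
        index=[remap[c] for c in ordered],
        columns=trends.columns,
    )
    return MetaregulonClustering(
        labels=final,
        metaregulon_trends=mt,
        metric="cosine",
        n_neighbors=k,
        resolution=resolution,
    )


def bin_summaries(
    values,
    pseudotime: np.ndarray,
    n_bins: int = 20,
    segment: np.ndarray | None = None,
    per_segment: bool = False,
) -> pd.DataFrame:
    """Mean feature value in equal-width pseudotime bins.

    Global mode uses ``n_bins`` bins over the full pseudotime range; with
    ``per_segment`` every segment gets its own ``n_bins`` equal-width bins
    (columns labelled ``segment:bin``). Empty bins are NaN.
    """
    if isinstance(values, pd.DataFrame):
        names, Y = list(values.index), values.to_numpy(float)
    else:
        Y = np.asarray(values, float)
        if Y.ndim == 1:
            Y = Y[None, :]
        names = [f"feature{i}" for i in range(Y.shape[0])]
    t = np.asarray(pseudotime, float)
    if Y.shape[1] != len(t):
        raise ValueError("pseudotime length does not match the value matrix")
    if n_bins > len(t):
        warnings.warn(f"n_bins={n_bins} exceeds cell count {len(t)}; expect empty bins")

    def _bin_block(tv, block, prefix=""):
        lo, hi = tv.min(), tv.max()
        edges = np.linspace(lo, hi, n_bins + 1) if hi > lo else np.linspace(lo, lo + 1, n_bins + 1)
        which = np.clip(np.digitize(tv, edges[1:-1]), 0, n_bins - 1)
        cols = {}
        for b in range(n_bins):
            m = which == b
            cols[f"{prefix}{b}"] = block[:, m].mean(axis=1) if m.any() else np.full(block.shape[0], np.nan)
        return cols

    data = {}
    if per_segment:
        if segment is None:
            raise ValueError("per_segment binning requires segment labels")
        seg = np.asarray(segment)
        for s in sorted(set(seg.tolist()), key=str):
            m = seg == s
            data.update(_bin_block(t[m], Y[:, m], prefix=f"{s}:"))
    else:
        data.update(_bin_block(t, Y))
    return pd.DataFrame(data, index=names)
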