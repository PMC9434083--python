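"""Correlation-kNN mapping of query profiles onto a reference trajectory.

Each query sample (a cell or a bulk profile) is correlated against every
reference cell over their shared feature space; its k most-correlated
reference cells become weighted neighbors. Queries are then projected into the
reference embedding as the weighted average of neighbor coordinates, and
labels / scalar values (e.g. pseudotime) are propagated the same way. Weights
are the neighbor correlations shifted to be positive (minimum neighbor
correlation subtracted, small epsilon added) and normalized to sum one; the
scheme is transparent and recorded in the graph object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("crestflow")

__all__ = ["TransferGraph", "correlation_knn", "project_and_propagate"]

MIN_SHARED_FEATURES = 50
_EPS = 1e-6


@dataclass
class TransferGraph:
    query_ids: list[str]
    reference_ids: list[str]
    neighbors: np.ndarray  # queries x k reference indices
    weights: np.ndarray  # queries x k, rows sum to 1
    correlations: np.ndarray  # queries x k raw Pearson correlations
    k: int
    features_used: list[str]

    def edge_frame(self) -> pd.DataFrame:
        rows = []
        for qi, q in enumerate(self.query_ids):
            for j in range(self.k):
                rows.append(
                    {
                        "query": q,
                        "neighbor": self.reference_ids[self.neighbors[qi, j]],
                        "correlation": self.correlations[qi, j],
                        "weight": self.weights[qi, j],
                    }
                )
        return pd.DataFrame(rows)


def correlation_knn(
    query: pd.DataFrame,
    reference: pd.DataFrame,
    k: int = 5,
    exclude_genes=None,
) -> TransferGraph:
    """Build the query-to-reference correlation kNN graph.

    ``query`` and ``reference`` are feature x sample frames; features are
    intersected (minus ``exclude_genes``, e.g. a cell-cycle-correlated list
    supplied by the caller) and require at least 50 in common.
    """
    shared = [g for g in query.index if g in set(reference.index)]
    if exclude_genes is not None:
        drop = set(exclude_genes)
        shared = [g for g in shared if g not in drop]
    if len(shared) < MIN_SHARED_FEATURES:
        raise ValueError(
            f"only {len(shared)} shared features after intersection/exclusion; "
            f"need at least {MIN_SHARED_FEATURES}"
        )
    Q = query.loc[shared].to_numpy(float)
    Rf = reference.loc[shared].to_numpy(float)
    if k < 1 or k > Rf.shape[1]:
        raise ValueError(f"k={k} out of range for {Rf.shape[1]} reference cells")

    def _std(M):
        mu = M.mean(axis=0, keepdims=True)
        sd = M.std(axis=0, keepdims=True)
        sd = np.where(sd > 0, sd, 1.0)
        return (M - mu) / sd

    C = _std(Q).T @ _std(Rf) / len(shared)  # queries x reference cells
    C = np.nan_to_num(C, nan=-1.0)
    order = np.argsort(-C, axis=1, kind="mergesort")[:, :k]
    corr = np.take_along_axis(C, order, axis=1)
    shifted = corr - corr.min(axis=1, keepdims=True) + _EPS
    weights = shifted / shifted.sum(axis=1, keepdims=True)
    return TransferGraph(
        query_ids=list(map(str, query.columns)),
        reference_ids=list(map(str, reference.columns)),
        neighbors=order,
        weights=weights,
        correlations=corr,
        k=k,
        features_used=shared,
    )


def project_and_propagate(
    graph: TransferGraph,
    reference_coords: np.ndarray,
    reference_labels=None,
    reference_values=None,
) -> pd.DataFrame:
    """Weighted-average projection and label/value propagation.

    Projected coordinates are the weight-weighted average of neighbor
    coordinates (hence inside their convex hull); a transferred value is the
    weighted average of neighbor values; the transferred label is the label
    with the largest summed weight (exact ties resolve to the
    lexicographically first label and are flagged).
    """
    coords = np.asarray(reference_coords, float)
    if coords.shape[0] != len(graph.reference_ids):
        raise ValueError("reference_coords do not cover all reference cells")
    n_q, k = graph.neighbors.shape
    proj = np.einsum("qk,qkd->qd", graph.weights, coords[graph.neighbors])
    out = pd.DataFrame(
        proj, index=graph.query_ids, columns=[f"dim{d}" for d in range(coords.shape[1])]
    )
    if reference_values is not None:
        vals = np.asarray(reference_values, float)
        out["value"] = (graph.weights * vals[graph.neighbors]).sum(axis=1)
    if reference_labels is not None:
        labs = np.asarray(reference_labels)
        transferred, tied = [], []
        for qi in range(n_q):
            agg: dict[str, float] = {}
            for j in range(k):
                lab = str(labs[graph.neighbors[qi, j]])
                agg[lab] = agg.get(lab, 0.0) + float(graph.weights[qi, j])
            top = max(agg.values())
            winners = sorted(l for l, w in agg.items() if abs(w - top) <= 1e-12)
            transferred.append(winners[0])
            tied.append(len(winners) > 1)
        out["label"] = transferred
        out["label_tied"] = tied
    return out
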