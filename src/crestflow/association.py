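"""Testing features for association with the tree and fitting smooth trends.

For every feature (gene expression or regulon activity) the tree-dependent
model — a cubic-spline function of pseudotime fitted independently per tree
segment — is compared with the intercept-only model by an F-test on residual
sums of squares. P-values are Benjamini–Hochberg corrected across features; a
feature is called significant when its q-value clears the FDR threshold *and*
the amplitude of its fitted trend (max minus min of fitted values) exceeds
``a_cut``, which filters out statistically detectable but flat features.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("crestflow")

__all__ = [
    "natural_spline_basis",
    "AssociationResult",
    "FittedTrend",
    "test_association",
    "fit_trends",
]


def natural_spline_basis(
    x: np.ndarray, df: int = 5, knots: np.ndarray | None = None
) -> np.ndarray:
    """Natural cubic spline basis (no intercept column), ``df`` columns.

    Knots default to ``df + 1`` quantile-spaced points including the range
    boundaries. The basis contains ``x`` itself, so linear functions are
    represented exactly; the fit is linear beyond the boundary knots.
    """
    x = np.asarray(x, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    if knots is None:
        qs = np.linspace(0.0, 1.0, df + 1)
        knots = np.unique(np.quantile(x, qs))
    knots = np.asarray(knots, dtype=float)
    K = len(knots)
    if K < 2:
        # degenerate covariate: only the linear column (itself constant)
        return x[:, None].copy()

    def d(k: int) -> np.ndarray:
        num = np.maximum(x - knots[k], 0.0) ** 3 - np.maximum(x - knots[-1], 0.0) ** 3
        return num / (knots[-1] - knots[k])

    cols = [x]
    last = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - last)
    return np.column_stack(cols)


@dataclass
class AssociationResult:
    """Per-feature association statistics."""

    table: pd.DataFrame  # feature, F, p, q, amplitude, significant, degenerate
    spline_df: int
    fdr_threshold: float
    a_cut: float
    n_cells_used: int
    dropped_segments: list[int]

    def significant_features(self) -> list[str]:
        return self.table.loc[self.table["significant"], "feature"].tolist()


@dataclass
class FittedTrend:
    """Per-feature fitted values on a per-segment pseudotime grid."""

    features: list[str]
    segments: list[int]
    grid: dict[int, np.ndarray]  # segment -> strictly increasing pseudotime grid
    values: dict[int, np.ndarray]  # segment -> features x grid fitted values
    spline_df: int

    def long_frame(self) -> pd.DataFrame:
        rows = []
        for seg in self.segments:
            g = self.grid[seg]
            v = self.values[seg]
            for fi, f in enumerate(self.features):
                rows.append(
                    pd.DataFrame(
                        {"feature": f, "segment": seg, "grid_t": g, "fitted": v[fi]}
                    )
                )
        return pd.concat(rows, ignore_index=True)

    def feature_values(self, feature: str, segment: int) -> np.ndarray:
        return self.values[segment][self.features.index(feature)]

    def amplitude(self, feature: str) -> float:
        fi = self.features.index(feature)
        allv = np.concatenate([self.values[s][fi] for s in self.segments])
        return float(allv.max() - allv.min())


def _segment_design(
    t: np.ndarray, segment: np.ndarray, spline_df: int, min_cells: int
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Block design: per-segment intercept + spline basis; returns
    (X, included-cell mask, dropped segment ids)."""
    segs = sorted(set(segment.tolist()), key=str)
    dropped = []
    blocks, mask = [], np.zeros(len(t), dtype=bool)
    for s in segs:
        m = segment == s
        if m.sum() < min_cells:
            dropped.append(s)
            continue
        mask |= m
    if not mask.any():
        raise ValueError("no segment has enough cells for the spline fit")
    for s in segs:
        if s in dropped:
            continue
        m = segment == s
        B = natural_spline_basis(t[m], df=spline_df)
        block = np.zeros((len(t), B.shape[1] + 1))
        block[m, 0] = 1.0
        block[m, 1:] = B
        blocks.append(block)
    X = np.column_stack(blocks)[mask]
    return X, mask, dropped


def test_association(
    features,
    pseudotime,
    segment: np.ndarray | None = None,
    spline_df: int = 5,
    fdr_threshold: float = 1e-4,
    a_cut: float = 0.025,
) -> AssociationResult:
    """F-test of the per-segment spline model against the global intercept.

    Parameters
    ----------
    features
        ``(n_features, n_cells)`` array or DataFrame (rows = features).
    pseudotime
        A :class:`~crestflow.tree.PseudotimeField`, or a per-cell pseudotime
        array (then ``segment`` must be given or defaults to one segment).
    """
    names, Y = _as_matrix(features)
    t, seg = _as_pt(pseudotime, segment, Y.shape[1])
    if spline_df < 3:
        raise ValueError("spline_df must be >= 3 for a cubic spline")
    X, mask, dropped = _segment_design(t, seg, spline_df, min_cells=spline_df + 2)
    if dropped:
        warnings.warn(f"segments {dropped} dropped (fewer than {spline_df + 2} cells)")
    Yk = Y[:, mask]
    n = Yk.shape[1]
    beta, _, rank, _ = np.linalg.lstsq(X, Yk.T, rcond=None)
    fitted = (X @ beta).T  # features x n
    rss1 = ((Yk - fitted) ** 2).sum(axis=1)
    ybar = Yk.mean(axis=1, keepdims=True)
    rss0 = ((Yk - ybar) ** 2).sum(axis=1)

    p_full = int(rank)
    df1 = max(p_full - 1, 1)
    df2 = max(n - p_full, 1)
    degenerate = rss0 <= 1e-12 * np.maximum(np.abs(ybar).ravel() ** 2 * n, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss0 - rss1) / df1) / (rss1 / df2)
    F = np.where(degenerate, 0.0, F)
    pvals = np.where(
        degenerate,
        1.0,
        np.where(rss1 <= 1e-300, 0.0, stats.f.sf(np.maximum(F, 0.0), df1, df2)),
    )
    amplitude = np.where(degenerate, 0.0, fitted.max(axis=1) - fitted.min(axis=1))
    _, q, _, _ = multipletests(pvals, method="fdr_bh")
    significant = (q < fdr_threshold) & (amplitude > a_cut)
    table = pd.DataFrame(
        {
            "feature": names,
            "F": F,
            "p": pvals,
            "q": q,
            "amplitude": amplitude,
            "significant": significant,
            "degenerate": degenerate,
        }
    )
    return AssociationResult(
        table=table,
        spline_df=spline_df,
        fdr_threshold=fdr_threshold,
        a_cut=a_cut,
        n_cells_used=n,
        dropped_segments=dropped,
    )


def fit_trends(
    features,
    pseudotime,
    segment: np.ndarray | None = None,
    spline_df: int = 5,
    grid_size: int = 50,
) -> FittedTrend:
    """Per-segment cubic-spline fits evaluated on equal-spaced grids.

    Each segment's grid spans its observed pseudotime range; evaluating the
    trend outside that range clamps to the boundary value.
    """
    names, Y = _as_matrix(features)
    t, seg = _as_pt(pseudotime, segment, Y.shape[1])
    segs = sorted(set(seg.tolist()), key=str)
    grid, values = {}, {}
    kept_segments = []
    for s in segs:
        m = seg == s
        ts = t[m]
        if m.sum() < spline_df + 2:
            warnings.warn(f"segment {s} has too few cells to fit; skipped")
            continue
        lo, hi = float(ts.min()), float(ts.max())
        if hi <= lo:
            warnings.warn(f"segment {s} has zero pseudotime range; skipped")
            continue
        qs = np.linspace(0.0, 1.0, spline_df + 1)
        knots = np.unique(np.quantile(ts, qs))
        B = natural_spline_basis(ts, df=spline_df, knots=knots)
        X = np.column_stack([np.ones(B.shape[0]), B])
        beta, *_ = np.linalg.lstsq(X, Y[:, m].T, rcond=None)
        g = np.linspace(lo, hi, grid_size)
        Bg = natural_spline_basis(g, df=spline_df, knots=knots)
        Xg = np.column_stack([np.ones(grid_size), Bg])
        grid[s] = g
        values[s] = (Xg @ beta).T
        kept_segments.append(s)
    if not kept_segments:
        raise ValueError("no segment could be fitted")
    return FittedTrend(
        features=list(names),
        segments=kept_segments,
        grid=grid,
        values=values,
        spline_df=spline_df,
    )


def _as_matrix(features) -> tuple[list[str], np.ndarray]:
    if isinstance(features, pd.DataFrame):
        return list(map(str, features.index)), features.to_numpy(dtype=float)
    Y = np.asarray(features, dtype=float)
    if Y.ndim == 1:
        Y = Y[None, :]
    return [f"feature{i}" for i in range(Y.shape[0])], Y


def _as_pt(pseudotime, segment, n_cells) -> tuple[np.ndarray, np.ndarray]:
    # duck-typed PseudotimeField
    if hasattr(pseudotime, "cell_pseudotime"):
        t = np.asarray(pseudotime.cell_pseudotime, float)
        seg = np.asarray(pseudotime.cell_segment)
    else:
        t = np.asarray(pseudotime, float)
        seg = np.zeros(len(t), dtype=int) if segment is None else np.asarray(segment)
    if len(t) != n_cells or len(seg) != n_cells:
        raise ValueError("pseudotime/segment length does not match the feature matrix")
    return t, seg
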