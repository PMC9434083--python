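"""Local (windowed) correlation analysis of competing gene modules.

Cells are ordered by pseudotime and grouped into sliding or non-intersecting
windows. Within each window the gene-gene Pearson correlation matrix over the
members of two fate modules is computed; the intra-module correlation is the
mean over distinct unordered pairs inside one module, the inter-module
correlation the mean over all cross-module pairs. Tracking these along
pseudotime exposes the fate-choice signature: competing early modules are
positively coupled while co-activating before the fork, then anti-correlated
as the branches commit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tree import PrincipalTree, extract_path, compute_pseudotime, probabilistic_mappings

logger = logging.getLogger("crestflow")

__all__ = [
    "GeneModule",
    "Window",
    "WindowSeries",
    "make_windows",
    "window_module_correlations",
    "correlations_over_mappings",
]


@dataclass(frozen=True)
class GeneModule:
    name: str
    genes: tuple[str, ...]
    branch: str | None = None

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError(f"module {self.name} has no genes")


@dataclass(frozen=True)
class Window:
    index: int
    cell_indices: np.ndarray
    t_span: tuple[float, float]


@dataclass
class WindowSeries:
    windows: list[Window]
    scheme: str  # 'sliding' | 'nonintersecting'
    window_size: int
    step: int | None

    def __len__(self) -> int:
        return len(self.windows)

    def centers(self) -> np.ndarray:
        return np.array([(w.t_span[0] + w.t_span[1]) / 2.0 for w in self.windows])


def make_windows(
    pseudotime: np.ndarray,
    window_size: int,
    step: int | None = None,
    scheme: str = "sliding",
) -> WindowSeries:
    """Group pseudotime-ordered cells into windows.

    Sliding windows of ``window_size`` cells advance by ``step``; the final
    window is anchored at the last cell if a full step would overshoot.
    Non-intersecting windows partition the ordering into consecutive blocks
    (a trailing block is kept if at least half-sized).
    """
    t = np.asarray(pseudotime, float)
    n = len(t)
    if window_size > n:
        raise ValueError(f"window_size {window_size} exceeds cell count {n}")
    if window_size < 10:
        warnings.warn("windows below 10 cells give unstable correlations")
    if scheme not in ("sliding", "nonintersecting"):
        raise ValueError(f"unknown scheme {scheme!r}")
    order = np.argsort(t, kind="mergesort")
    windows: list[Window] = []
    if scheme == "sliding":
        if step is None or step < 1:
            raise ValueError("sliding windows need step >= 1")
        starts = list(range(0, n - window_size + 1, step))
        for wi, s in enumerate(starts):
            idx = order[s : s + window_size]
            windows.append(Window(wi, idx, (float(t[idx].min()), float(t[idx].max()))))
    else:
        s = 0
        wi = 0
        while s < n:
            idx = order[s : s + window_size]
            if len(idx) < window_size and len(idx) < window_size / 2.0:
                break
            windows.append(Window(wi, idx, (float(t[idx].min()), float(t[idx].max()))))
            wi += 1
            s += window_size
    return WindowSeries(windows=windows, scheme=scheme, window_size=window_size, step=step)


def _pair_mean(corr: np.ndarray, rows: np.ndarray, cols: np.ndarray, same: bool) -> float:
    """Mean correlation over module pairs; NaN when no valid pair exists."""
    sub = corr[np.ix_(rows, cols)]
    if same:
        k = len(rows)
        if k < 2:
            return np.nan
        iu = np.triu_indices(k, k=1)
        vals = sub[iu]
    else:
        vals = sub.ravel()
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else np.nan


def window_module_correlations(
    values,
    gene_ids: list[str],
    windows: WindowSeries,
    module_a: GeneModule,
    module_b: GeneModule,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Intra- and inter-module mean local correlations per window.

    Returns ``(summary, gene_series)``: the summary has one row per window with
    intra_a, intra_b and inter means; gene_series holds each gene's mean local
    correlation with the members of the *other* module. Genes constant within
    a window are excluded from that window's pairs (logged), never imputed; a
    window with no valid pair is reported as NaN.
    """
    if set(module_a.genes) & set(module_b.genes):
        raise ValueError("modules must be disjoint")
    Y = np.asarray(values, float)
    lookup = {g: i for i, g in enumerate(gene_ids)}
    missing = [g for g in (*module_a.genes, *module_b.genes) if g not in lookup]
    if missing:
        raise KeyError(f"module genes absent from the matrix: {missing[:5]}")
    ia = np.array([lookup[g] for g in module_a.genes])
    ib = np.array([lookup[g] for g in module_b.genes])
    allidx = np.concatenate([ia, ib])
    a_pos = np.arange(len(ia))
    b_pos = np.arange(len(ia), len(ia) + len(ib))

    rows, gene_rows = [], []
    for w in windows.windows:
        if len(w.cell_indices) < 3:
            raise ValueError(f"window {w.index} has fewer than 3 cells")
        sub = Y[np.ix_(allidx, w.cell_indices)]
        sd = sub.std(axis=1)
        dead = sd <= 0
        if dead.any():
            logger.info(
                "window %d: %d constant genes excluded", w.index, int(dead.sum())
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(sub)
        corr[dead, :] = np.nan
        corr[:, dead] = np.nan
        rows.append(
            {
                "window_index": w.index,
                "t_center": (w.t_span[0] + w.t_span[1]) / 2.0,
                "intra_a": _pair_mean(corr, a_pos, a_pos, same=True),
                "intra_b": _pair_mean(corr, b_pos, b_pos, same=True),
                "inter": _pair_mean(corr, a_pos, b_pos, same=False),
            }
        )
        for gi, g in enumerate(module_a.genes):
            vals = corr[a_pos[gi], b_pos]
            vals = vals[np.isfinite(vals)]
            gene_rows.append(
                {"window_index": w.index, "gene": g, "module": module_a.name,
                 "other_module": module_b.name,
                 "mean_corr": float(vals.mean()) if vals.size else np.nan}
            )
        for gi, g in enumerate(module_b.genes):
            vals = corr[b_pos[gi], a_pos]
            vals = vals[np.isfinite(vals)]
            gene_rows.append(
                {"window_index": w.index, "gene": g, "module": module_b.name,
                 "other_module": module_a.name,
                 "mean_corr": float(vals.mean()) if vals.size else np.nan}
            )
    return pd.DataFrame(rows), pd.DataFrame(gene_rows)


def correlations_over_mappings(
    values,
    gene_ids: list[str],
    tree: PrincipalTree,
    from_milestone: int,
    to_milestones,
    module_a: GeneModule,
    module_b: GeneModule,
    n_mappings: int = 100,
    window_size: int = 50,
    step: int | None = None,
    scheme: str = "sliding",
    seed: int = 0,
) -> pd.DataFrame:
    """Window correlations aggregated over probabilistic cell-to-node mappings.

    Each mapping samples a hard node per cell from R, recomputes pseudotime
    ordering along the selected path and the window correlations, and the
    per-window-index mean and standard deviation across mappings is reported.
    With fully concentrated R every mapping coincides and the sd is zero.
    """
    if n_mappings < 2:
        warnings.warn("n_mappings < 2: standard deviations reported as 0")
    if tree.root is None:
        raise ValueError("tree has no root; run compute_pseudotime first")
    pt = compute_pseudotime(tree, tree.root, mode="soft")
    base_path = extract_path(tree, pt, from_milestone, to_milestones)
    node_labels = base_path.node_labels
    node_t = pt.node_pseudotime
    if step is None:
        step = max(window_size // 3, 1)
    mappings = probabilistic_mappings(tree, n_mappings=n_mappings, seed=seed)
    Y = np.asarray(values, float)
    acc: dict[tuple[int, str], list[float]] = {}
    for m in range(n_mappings):
        nodes = mappings[m]
        on_path = np.array([node_labels.get(int(x)) is not None for x in nodes])
        idx = np.flatnonzero(on_path)
        if len(idx) < max(window_size, 3):
            continue
        t_cells = node_t[nodes[idx]]
        windows = make_windows(t_cells, window_size=window_size, step=step, scheme=scheme)
        remapped = WindowSeries(
            windows=[
                Window(w.index, idx[w.cell_indices], w.t_span) for w in windows.windows
            ],
            scheme=windows.scheme,
            window_size=windows.window_size,
            step=windows.step,
        )
        summary, _ = window_module_correlations(Y, gene_ids, remapped, module_a, module_b)
        for _, row in summary.iterrows():
            for stat in ("intra_a", "intra_b", "inter"):
                acc.setdefault((int(row["window_index"]), stat), []).append(row[stat])
            acc.setdefault((int(row["window_index"]), "t_center"), []).append(
                row["t_center"]
            )
    rows = []
    widx = sorted({k[0] for k in acc})
    for wi in widx:
        t_c = float(np.nanmean(acc[(wi, "t_center")]))
        for stat in ("intra_a", "intra_b", "inter"):
            vals = np.asarray(acc.get((wi, stat), [np.nan]), float)
            vals = vals[np.isfinite(vals)]
            mean = float(vals.mean()) if vals.size else np.nan
            sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            rows.append(
                {"window_index": wi, "t_center": t_c, "statistic": stat,
                 "mean": mean, "sd": sd, "n_mappings": int(vals.size)}
            )
    return pd.DataFrame(rows)
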