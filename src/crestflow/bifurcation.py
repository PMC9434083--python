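"""Fork statistics: branch-specific genes and early/late activation timing.

Around a bifurcation, each gene is modelled as
``g ~ s(pseudotime) + s(pseudotime):Branch + Branch`` over the cells of the
two-branch path; the F-test on the smooth-by-branch interaction block detects
genes whose trend differs between the post-fork branches. Candidate genes are
then assigned to the branch along which the linear model ``g ~ pseudotime``
shows significant upregulation (positive slope, BH FDR < 0.05) and a
sufficient post-fork expression advantage over the other branch.

Activation timing splits the progenitor-to-terminal trend into bins and uses
the relative expression rate

    r(b) = (f(b+1) - f(b-1)) / (max f - min f)

with ``f(b)`` the mean fitted expression in bin ``b``. The first interior bin
whose rate exceeds a threshold marks the activation pseudotime; genes
activating at or before the fork are "early", after it "late".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .association import _as_matrix, natural_spline_basis
from .tree import ForkPath

logger = logging.getLogger("crestflow")

__all__ = [
    "test_fork",
    "assign_branch_specific",
    "activation_timing",
    "ActivationResult",
    "analyze_fork",
]

_BRANCHES = ("branch-1", "branch-2")


def _fork_arrays(features, fork_path: ForkPath):
    if isinstance(features, tuple):  # pre-extracted (names, matrix over path cells)
        names, Y = features[0], np.asarray(features[1], float)
    else:
        names, Y = _as_matrix(features)
    if Y.shape[1] == len(fork_path.cell_indices):
        sub = Y
    else:
        sub = Y[:, fork_path.cell_indices]
    return names, sub, fork_path.pseudotime, fork_path.branch_labels


def test_fork(
    features, fork_path: ForkPath, spline_df: int = 5, fdr_cut: float = 0.1
) -> pd.DataFrame:
    """Interaction F-test for branch-dependent trends.

    ``features`` may cover all cells (columns indexed by ``fork_path``) or just
    the path cells. Returns a per-gene table with the interaction F, p, BH q
    and a ``candidate`` flag (q < fdr_cut). Swapping branch labels leaves every
    p unchanged (the two codings span the same column space).
    """
    names, Y, t, labels = _fork_arrays(features, fork_path)
    if set(labels) & set(_BRANCHES) != set(_BRANCHES):
        raise ValueError(
            "fork_path must contain two post-fork branches; "
            "for a single path use test_association instead"
        )
    for b in _BRANCHES:
        if (labels == b).sum() < spline_df + 2:
            raise ValueError(f"{b} has fewer than {spline_df + 2} cells")
    S = natural_spline_basis(t, df=spline_df)
    one = np.ones((len(t), 1))
    # signed branch contrast (+1 / -1, 0 pre-fork): swapping labels flips the
    # sign of the branch columns, so the model span and p-values are symmetric
    b = ((labels == "branch-1").astype(float)
         - (labels == "branch-2").astype(float))[:, None]
    X_red = np.column_stack([one, S, b])
    X_full = np.column_stack([one, S, b, S * b])

    def _fit(X):
        beta, _, rank, _ = np.linalg.lstsq(X, Y.T, rcond=None)
        resid = Y.T - X @ beta
        return (resid**2).sum(axis=0), int(rank)

    rss_red, rank_red = _fit(X_red)
    rss_full, rank_full = _fit(X_full)
    df1 = max(rank_full - rank_red, 1)
    df2 = max(len(t) - rank_full, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss_red - rss_full) / df1) / (rss_full / df2)
    F = np.nan_to_num(np.maximum(F, 0.0))
    p = np.where(rss_full <= 1e-300, 0.0, stats.f.sf(F, df1, df2))
    const = Y.var(axis=1) <= 1e-300
    p = np.where(const, 1.0, p)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {"gene": names, "F": F, "p": p, "q": q, "candidate": q < fdr_cut}
    )


def assign_branch_specific(
    fork_stats: pd.DataFrame,
    features,
    fork_path: ForkPath,
    upreg_fdr: float = 0.05,
    effect_cutoff: float = 0.2,
    spline_df: int = 5,
) -> pd.DataFrame:
    """Assign candidate genes to the branch they are upregulated along.

    For each candidate and each branch, the linear model ``g ~ pseudotime`` is
    fitted over the progenitor-to-terminal path (pre-fork plus that branch).
    A gene is assigned to the branch where the slope is positive with BH
    FDR < ``upreg_fdr`` and the mean spline-fitted post-fork expression exceeds
    the other branch's by at least ``effect_cutoff``; otherwise it stays
    unassigned.
    """
    names, Y, t, labels = _fork_arrays(features, fork_path)
    name_to_row = {n: i for i, n in enumerate(names)}
    cand = fork_stats.loc[fork_stats["candidate"], "gene"].tolist()
    pre = labels == "pre-fork"
    out_rows = []
    per_branch: dict[str, dict[str, np.ndarray]] = {}
    for b in _BRANCHES:
        m = pre | (labels == b)
        tb = t[m]
        Yb = Y[:, m]
        tc = tb - tb.mean()
        stt = float((tc**2).sum())
        slopes = (Yb * tc[None, :]).sum(axis=1) / stt
        fitted = Yb.mean(axis=1, keepdims=True) + slopes[:, None] * tc[None, :]
        dof = len(tb) - 2
        s2 = ((Yb - fitted) ** 2).sum(axis=1) / dof
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = slopes / np.sqrt(s2 / stt)
        pvals = 2.0 * stats.t.sf(np.abs(np.nan_to_num(tstat)), dof)
        pvals = np.where(s2 <= 1e-300, np.where(np.abs(slopes) > 0, 0.0, 1.0), pvals)
        # smooth post-fork mean level per gene on this branch
        post = labels == b
        Bq = natural_spline_basis(tb, df=spline_df)
        Xb = np.column_stack([np.ones(len(tb)), Bq])
        beta, *_ = np.linalg.lstsq(Xb, Yb.T, rcond=None)
        fit_all = (Xb @ beta).T
        mask_post = (labels == b)[m]
        post_mean = fit_all[:, mask_post].mean(axis=1)
        per_branch[b] = {"slope": slopes, "p": pvals, "post_mean": post_mean}
    for b in _BRANCHES:
        idx = [name_to_row[g] for g in cand]
        praw = per_branch[b]["p"][idx]
        q = multipletests(praw, method="fdr_bh")[1] if len(praw) else np.array([])
        per_branch[b]["q_cand"] = dict(zip(cand, q))
    other = {"branch-1": "branch-2", "branch-2": "branch-1"}
    for g in cand:
        i = name_to_row[g]
        winner, winner_stats = None, None
        both = []
        for b in _BRANCHES:
            s = per_branch[b]
            qv = float(s["q_cand"][g])
            diff = float(s["post_mean"][i] - per_branch[other[b]]["post_mean"][i])
            ok = (s["slope"][i] > 0) and (qv < upreg_fdr) and (diff >= effect_cutoff)
            if ok:
                both.append((b, s["slope"][i], qv, diff))
        if len(both) == 1:
            winner, slope, qv, diff = both[0][0], both[0][1], both[0][2], both[0][3]
            winner_stats = (slope, qv, diff)
        elif len(both) == 2:
            logger.info("gene %s qualifies on both branches; left unassigned", g)
        out_rows.append(
            {
                "gene": g,
                "branch": winner,
                "slope": winner_stats[0] if winner else np.nan,
                "upreg_q": winner_stats[1] if winner else np.nan,
                "effect": winner_stats[2] if winner else np.nan,
            }
        )
    return pd.DataFrame(out_rows, columns=["gene", "branch", "slope", "upreg_q", "effect"])


@dataclass
class ActivationResult:
    bin: int | None  # 1-based activation bin
    pseudotime: float | None
    label: str  # 'early' | 'late' | 'not-activated'
    rates: np.ndarray  # relative expression rate at interior bins (index 1..n-2)
    bin_means: np.ndarray
    bin_centers: np.ndarray
    degenerate: bool = False


def activation_timing(
    trend_values: np.ndarray,
    grid_t: np.ndarray,
    fork_pseudotime: float,
    n_bins: int = 10,
    rate_threshold: float = 0.1,
) -> ActivationResult:
    """Binned relative-rate activation call for one fitted trend.

    The trend (fitted values over a progenitor-to-terminal grid) is split into
    ``n_bins`` equal-width pseudotime bins; ``f(b)`` is the mean fitted value
    in bin ``b``. The gene activates at the first interior bin whose rate
    ``(f(b+1) - f(b-1)) / (max f - min f)`` exceeds ``rate_threshold``; the
    activation pseudotime is that bin's center. A flat trend (max f = min f)
    is degenerate and reported not-activated.
    """
    f = np.asarray(trend_values, float)
    t = np.asarray(grid_t, float)
    if len(f) != len(t):
        raise ValueError("trend and grid lengths differ")
    if len(f) < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} grid points, got {len(f)}")
    lo, hi = t.min(), t.max()
    edges = np.linspace(lo, hi, n_bins + 1)
    which = np.clip(np.digitize(t, edges[1:-1]), 0, n_bins - 1)
    bin_means = np.array([f[which == b].mean() for b in range(n_bins)])
    centers = 0.5 * (edges[:-1] + edges[1:])
    rng = bin_means.max() - bin_means.min()
    if rng <= 0:
        return ActivationResult(
            None, None, "not-activated", np.zeros(max(n_bins - 2, 0)), bin_means, centers, True
        )
    rates = (bin_means[2:] - bin_means[:-2]) / rng
    hits = np.flatnonzero(rates > rate_threshold)
    if hits.size == 0:
        return ActivationResult(None, None, "not-activated", rates, bin_means, centers)
    b0 = int(hits[0]) + 1  # interior bin index (0-based); 1-based bin number below
    t_act = float(centers[b0])
    label = "early" if t_act <= fork_pseudotime else "late"
    return ActivationResult(b0 + 1, t_act, label, rates, bin_means, centers)


def analyze_fork(
    features,
    fork_path: ForkPath,
    spline_df: int = 5,
    fdr_cut: float = 0.1,
    upreg_fdr: float = 0.05,
    effect_cutoff: float = 0.2,
    n_bins: int = 10,
    rate_threshold: float = 0.1,
    grid_size: int = 100,
) -> pd.DataFrame:
    """End-to-end fork report: interaction test, branch assignment, timing.

    Returns one row per gene with columns gene, p, q, branch, slope, upreg_q,
    activation_bin, activation_t, timing.
    """
    names, Y, t, labels = _fork_arrays(features, fork_path)
    stats_df = test_fork((names, Y), fork_path, spline_df=spline_df, fdr_cut=fdr_cut)
    assign = assign_branch_specific(
        stats_df, (names, Y), fork_path,
        upreg_fdr=upreg_fdr, effect_cutoff=effect_cutoff, spline_df=spline_df,
    )
    report = stats_df.merge(assign, on="gene", how="left")
    pre = labels == "pre-fork"
    act_bin, act_t, timing = [], [], []
    trend_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for b in _BRANCHES:
        m = pre | (labels == b)
        tb = t[m]
        qs = np.linspace(0, 1, spline_df + 1)
        knots = np.unique(np.quantile(tb, qs))
        B = natural_spline_basis(tb, df=spline_df, knots=knots)
        X = np.column_stack([np.ones(len(tb)), B])
        beta, *_ = np.linalg.lstsq(X, Y[:, m].T, rcond=None)
        g = np.linspace(tb.min(), tb.max(), grid_size)
        Bg = natural_spline_basis(g, df=spline_df, knots=knots)
        Xg = np.column_stack([np.ones(grid_size), Bg])
        trend_cache[b] = (g, (Xg @ beta).T)
    name_to_row = {n: i for i, n in enumerate(names)}
    for _, row in report.iterrows():
        b = row.get("branch")
        if not isinstance(b, str):
            act_bin.append(None)
            act_t.append(np.nan)
            timing.append("not-assigned")
            continue
        g, fits = trend_cache[b]
        res = activation_timing(
            fits[name_to_row[row["gene"]]], g, fork_path.fork_pseudotime,
            n_bins=n_bins, rate_threshold=rate_threshold,
        )
        act_bin.append(res.bin)
        act_t.append(res.pseudotime if res.pseudotime is not None else np.nan)
        timing.append(res.label)
    report["activation_bin"] = act_bin
    report["activation_t"] = act_t
    report["timing"] = timing
    return report
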