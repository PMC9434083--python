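"""Cell-level quality control and preprocessing.

Implements the standard deep-plate scRNA-seq front end: cell filtering on
transcript counts, detected genes and ERCC spike-in fraction; library-size
normalization with log transform; overdispersed-gene selection via a
mean-variance trend; and kNN smoothing over a cell graph as a light-weight
imputation step.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import kneighbors_graph

logger = logging.getLogger("crestflow")

_LAYERS = ("counts", "normalized", "log", "imputed")


@dataclass
class ExpressionMatrix:
    """Genes x cells expression values with ERCC spike-in annotation.

    Parameters
    ----------
    values
        Dense ``(n_genes, n_cells)`` array. Counts for ``layer='counts'``,
        otherwise finite floats.
    gene_ids, cell_ids
        Unique identifiers along each axis.
    ercc_mask
        Per-gene boolean, True for spike-in control rows.
    layer
        One of ``counts | normalized | log | imputed``.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    ercc_mask: np.ndarray
    layer: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        self.ercc_mask = np.asarray(self.ercc_mask, dtype=bool)
        if self.layer not in _LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {_LAYERS}")
        ng, nc = self.values.shape
        if len(self.gene_ids) != ng or len(self.cell_ids) != nc:
            raise ValueError(
                f"id lengths ({len(self.gene_ids)}, {len(self.cell_ids)}) do not "
                f"match matrix shape {self.values.shape}"
            )
        if self.ercc_mask.shape != (ng,):
            raise ValueError("ercc_mask length must equal the number of genes")
        if len(set(self.gene_ids)) != ng:
            raise ValueError("gene ids are not unique")
        if len(set(self.cell_ids)) != nc:
            raise ValueError("cell ids are not unique")
        if self.layer == "counts":
            if np.any(self.values < 0):
                raise ValueError("counts must be nonnegative")
        elif not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.layer} layer contains non-finite values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes not present: {missing[:5]}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_cells(self, keep) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        elif keep.dtype.kind in "iu":
            idx = keep
        else:
            lookup = {c: i for i, c in enumerate(self.cell_ids)}
            idx = np.array([lookup[c] for c in keep], dtype=int)
        return replace(
            self,
            values=self.values[:, idx],
            cell_ids=[self.cell_ids[i] for i in idx],
        )

    def subset_genes(self, keep) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        elif keep.dtype.kind in "iu":
            idx = keep
        else:
            idx = self.gene_index(keep)
        return replace(
            self,
            values=self.values[idx, :],
            gene_ids=[self.gene_ids[i] for i in idx],
            ercc_mask=self.ercc_mask[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass(frozen=True)
class QCThresholds:
    """Cell-retention thresholds.

    A cell is kept iff its non-ERCC transcript total lies in
    ``[min_transcripts, max_transcripts]``, its detected (non-ERCC) gene count
    lies in ``[min_genes, max_genes]`` and its ERCC read fraction is at most
    ``max_ercc_fraction``.
    """

    min_transcripts: float = 5e4
    max_transcripts: float = 6e6
    min_genes: int = 1000
    max_genes: int = 10000
    max_ercc_fraction: float = 0.15

    def __post_init__(self) -> None:
        if self.min_transcripts > self.max_transcripts:
            raise ValueError("min_transcripts > max_transcripts")
        if self.min_genes > self.max_genes:
            raise ValueError("min_genes > max_genes")
        if not 0.0 <= self.max_ercc_fraction <= 1.0:
            raise ValueError("max_ercc_fraction must lie in [0, 1]")


def filter_cells(
    matrix: ExpressionMatrix, thresholds: QCThresholds | None = None
) -> tuple[list[str], pd.DataFrame]:
    """Apply QC thresholds; return kept cell ids and a per-cell report.

    The report lists, per cell, the transcript total (non-ERCC), detected gene
    count, ERCC fraction, whether the cell was kept, and the failed criteria.
    """
    if thresholds is None:
        thresholds = QCThresholds()
    if matrix.layer != "counts":
        raise ValueError(f"filter_cells requires the counts layer, got {matrix.layer!r}")
    if matrix.n_cells == 0:
        warnings.warn("filter_cells called on an empty matrix")
        return [], pd.DataFrame(
            columns=["cell_id", "transcripts", "genes", "ercc_fraction", "kept", "reason"]
        )
    endo = matrix.values[~matrix.ercc_mask, :]
    ercc = matrix.values[matrix.ercc_mask, :]
    transcripts = endo.sum(axis=0)
    genes = (endo > 0).sum(axis=0)
    total = transcripts + (ercc.sum(axis=0) if ercc.size else 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ercc_frac = np.where(total > 0, (ercc.sum(axis=0) if ercc.size else 0.0) / np.maximum(total, 1), 0.0)

    th = thresholds
    reasons = []
    for i in range(matrix.n_cells):
        r = []
        if not th.min_transcripts <= transcripts[i] <= th.max_transcripts:
            r.append("transcripts")
        if not th.min_genes <= genes[i] <= th.max_genes:
            r.append("genes")
        if ercc_frac[i] > th.max_ercc_fraction:
            r.append("ercc_fraction")
        reasons.append(";".join(r))
    kept = np.array([r == "" for r in reasons])
    report = pd.DataFrame(
        {
            "cell_id": matrix.cell_ids,
            "transcripts": transcripts,
            "genes": genes,
            "ercc_fraction": ercc_frac,
            "kept": kept,
            "reason": reasons,
        }
    )
    kept_ids = [c for c, k in zip(matrix.cell_ids, kept) if k]
    logger.info("filter_cells kept %d / %d cells", len(kept_ids), matrix.n_cells)
    return kept_ids, report


def normalize_log(
    matrix: ExpressionMatrix, target_sum: float = 1e6, log_base: float = 10.0
) -> ExpressionMatrix:
    """Scale each cell to ``target_sum`` non-ERCC transcripts, then log(1+x).

    ERCC rows are excluded from the library size but are scaled by the same
    per-cell factor. Cells with zero non-ERCC total are dropped with a warning.
    """
    if matrix.layer != "counts":
        raise ValueError(f"normalize_log requires the counts layer, got {matrix.layer!r}")
    if target_sum <= 0:
        raise ValueError("target_sum must be positive")
    totals = matrix.values[~matrix.ercc_mask, :].sum(axis=0)
    nonzero = totals > 0
    if not np.all(nonzero):
        warnings.warn(f"dropping {int((~nonzero).sum())} zero-total cells during normalization")
        matrix = matrix.subset_cells(nonzero)
        totals = totals[nonzero]
    factors = target_sum / totals
    scaled = matrix.values * factors[None, :]
    logged = np.log1p(scaled) / np.log(log_base)
    return replace(matrix, values=logged, layer="log")


def select_overdispersed(matrix: ExpressionMatrix, n_top: int) -> pd.DataFrame:
    """Rank genes by excess variance over the mean-variance trend.

    Fits a degree-2 polynomial of log10 variance on log10 mean across genes of
    the log layer; the residual (observed minus trend) ranks genes. ERCC rows
    and zero-variance genes are never selected. Returns at most ``n_top`` genes
    with positive residuals, descending.
    """
    if matrix.layer not in ("log", "normalized"):
        raise ValueError("select_overdispersed expects a log or normalized layer")
    if matrix.n_genes < 10:
        raise ValueError("need at least 10 genes to fit a dispersion trend")
    vals = matrix.values
    means = vals.mean(axis=1)
    variances = vals.var(axis=1)
    usable = (~matrix.ercc_mask) & (variances > 0) & (means > 0)
    log_mean = np.log10(means[usable])
    log_var = np.log10(variances[usable])
    coefs = np.polyfit(log_mean, log_var, deg=2)
    trend = np.polyval(coefs, log_mean)
    residual = log_var - trend
    table = pd.DataFrame(
        {
            "gene_id": np.array(matrix.gene_ids)[usable],
            "mean": means[usable],
            "variance": variances[usable],
            "residual": residual,
        }
    )
    table = table[table["residual"] > 0].sort_values(
        ["residual", "gene_id"], ascending=[False, True], kind="mergesort"
    )
    if n_top > matrix.n_genes:
        warnings.warn(
            f"n_top={n_top} exceeds gene count {matrix.n_genes}; returning all candidates"
        )
    return table.head(n_top).reset_index(drop=True)


def build_knn_graph(embedding: np.ndarray, n_neighbors: int = 15) -> sp.csr_matrix:
    """Unweighted directed kNN connectivity graph over cells (rows)."""
    embedding = np.asarray(embedding, dtype=float)
    return kneighbors_graph(embedding, n_neighbors=n_neighbors, mode="connectivity")


def knn_smooth(
    matrix: ExpressionMatrix, neighbor_graph, steps: int = 1
) -> ExpressionMatrix:
    """Diffuse expression over the cell kNN graph.

    The transition operator is the row-normalized adjacency with a self-loop
    added to every cell; ``steps`` applications are performed. ``steps=0``
    returns the input values unchanged (relabelled as imputed). Smoothing is
    linear in the expression values.
    """
    if steps < 0:
        raise ValueError("steps must be >= 0")
    A = sp.csr_matrix(neighbor_graph, dtype=float)
    if A.shape[0] != matrix.n_cells or A.shape[1] != matrix.n_cells:
        raise ValueError(
            f"neighbor graph shape {A.shape} does not match {matrix.n_cells} cells"
        )
    if steps == 0:
        return replace(matrix, values=matrix.values.copy(), layer="imputed")
    deg = np.asarray(A.sum(axis=1)).ravel()
    if np.any(deg == 0):
        warnings.warn(
            f"{int((deg == 0).sum())} cells have no neighbors; self-loop only"
        )
    A = A + sp.identity(matrix.n_cells, format="csr")
    rowsum = np.asarray(A.sum(axis=1)).ravel()
    P = sp.diags(1.0 / rowsum) @ A
    out = matrix.values.astype(float)
    for _ in range(steps):
        out = np.asarray((P @ out.T).T)
    return replace(matrix, values=out, layer="imputed")
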