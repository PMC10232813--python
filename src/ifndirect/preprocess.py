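"""Cell QC, depth normalization, variable-gene selection and gene scaling.

The preprocessing contract mirrors the standard droplet scRNA-seq recipe:

1. retain cells with 200–2,000 uniquely detected genes (inclusive) and
   < 1 % mitochondrial counts (strict), mitochondrial genes being those whose
   symbol starts with ``mt-`` (murine convention, case-insensitive);
2. scale each cell's total transcript count to 10,000 and natural-log
   transform (``ln(1 + x)``);
3. select 3,000 highly variable genes by variance-stabilizing transformation:
   a local polynomial trend of log10 variance on log10 mean of the raw
   counts (span 0.3), standardization of each gene by its trend-predicted
   standard deviation with values clipped at sqrt(n_cells), and ranking by
   the variance of the standardized values;
4. z-score ("scale and center") selected genes across cells, clipped at ±10.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "QCThresholds",
    "NormalizedMatrix",
    "ScaledMatrix",
    "mito_gene_mask",
    "qc_stats",
    "filter_cells",
    "normalize",
    "find_variable_genes",
    "scale_genes",
]


@dataclass(frozen=True)
class QCThresholds:
    """Cell-retention bounds; defaults follow the source study exactly."""

    min_genes: int = 200
    max_genes: int = 2000
    max_pct_mito: float = 1.0

    def __post_init__(self):
        if self.min_genes > self.max_genes:
            raise ValueError("min_genes > max_genes")
        if not 0.0 < self.max_pct_mito <= 100.0:
            raise ValueError("max_pct_mito must be in (0, 100]")


@dataclass
class NormalizedMatrix:
    """Depth-normalized expression (genes x cells), linear or log scale."""

    values: sp.csr_matrix
    gene_names: list[str]
    barcodes: list[str]
    scale_total: float = 10_000.0
    is_log: bool = False

    def log1p(self) -> "NormalizedMatrix":
        if self.is_log:
            raise ValueError("matrix is already log-transformed")
        out = self.values.copy()
        out.data = np.log1p(out.data)
        return NormalizedMatrix(out, self.gene_names, self.barcodes,
                                self.scale_total, is_log=True)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_names)}

    def subset_cells(self, mask_or_idx) -> "NormalizedMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return NormalizedMatrix(self.values[:, idx], self.gene_names,
                                [self.barcodes[i] for i in idx],
                                self.scale_total, self.is_log)


@dataclass
class ScaledMatrix:
    """Dense z-scored expression of a gene subset (genes x cells)."""

    values: np.ndarray
    gene_names: list[str]
    barcodes: list[str] = field(default_factory=list)


def mito_gene_mask(gene_names) -> np.ndarray:
    return np.array([g.lower().startswith("mt-") for g in gene_names])


def qc_stats(cm: CountMatrix) -> pd.DataFrame:
    """Per-cell detected genes, totals and mitochondrial percentage."""
    counts = cm.counts.tocsc()
    totals = np.asarray(counts.sum(axis=0)).ravel()
    detected = np.diff(counts.indptr)  # nnz per column == genes detected
    mito = mito_gene_mask(cm.gene_names)
    mito_totals = np.asarray(counts[mito, :].sum(axis=0)).ravel() \
        if mito.any() else np.zeros_like(totals)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(totals > 0, 100.0 * mito_totals / totals, 0.0)
    return pd.DataFrame({
        "barcode": cm.barcodes,
        "n_genes_detected": detected.astype(int),
        "total_counts": totals.astype(int),
        "pct_mito": pct,
    })


def filter_cells(cm: CountMatrix,
                 thresholds: QCThresholds = QCThresholds()
                 ) -> tuple[CountMatrix, pd.DataFrame]:
    """Apply the QC gate; bounds inclusive on genes, strict on mito percent.

    Returns the filtered matrix and a QC table covering **all** input cells
    with a boolean ``kept`` column.  Raises if no cell survives, rather than
    silently producing an empty matrix.  Idempotent by construction.
    """
    stats = qc_stats(cm)
    kept = (
        (stats["n_genes_detected"] >= thresholds.min_genes)
        & (stats["n_genes_detected"] <= thresholds.max_genes)
        & (stats["pct_mito"] < thresholds.max_pct_mito)
    ).to_numpy()
    stats["kept"] = kept
    n_in, n_out = len(kept), int(kept.sum())
    logger.info("QC: kept %d / %d cells (%.1f%%)", n_out, n_in,
                100.0 * n_out / max(n_in, 1))
    if n_out == 0:
        raise ValueError(
            "empty after QC: no cell satisfies "
            f"[{thresholds.min_genes}, {thresholds.max_genes}] genes and "
            f"pct_mito < {thresholds.max_pct_mito}")
    return cm.subset_cells(kept), stats


def normalize(cm: CountMatrix, scale_total: float = 10_000.0
              ) -> NormalizedMatrix:
    """Scale each cell's counts so the cell total equals ``scale_total``."""
    counts = cm.counts.tocsc().astype(float)
    totals = np.asarray(counts.sum(axis=0)).ravel()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            "cannot normalize zero-total cell(s): "
            f"{[cm.barcodes[i] for i in zero[:5]]}")
    counts.data *= np.repeat(scale_total / totals, np.diff(counts.indptr))
    return NormalizedMatrix(counts.tocsr(), list(cm.gene_names),
                            list(cm.barcodes), scale_total, is_log=False)


# ---------------------------------------------------------------------------
# variance-stabilized HVG selection
# ---------------------------------------------------------------------------

def _loess_trend(x: np.ndarray, y: np.ndarray, span: float = 0.3,
                 degree: int = 2) -> np.ndarray:
    """Local weighted polynomial regression (tricube kernel), fitted at x."""
    n = len(x)
    k = max(degree + 2, int(np.ceil(span * n)))
    fitted = np.empty(n)
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    for pos, xi in enumerate(xs):
        d = np.abs(xs - xi)
        cutoff = np.partition(d, k - 1)[k - 1]
        w = np.zeros(n)
        in_win = d <= cutoff
        if cutoff > 0:
            w[in_win] = (1 - (d[in_win] / cutoff) ** 3) ** 3
        else:
            w[in_win] = 1.0
        sw = np.sqrt(w[in_win])
        X = np.vander(xs[in_win] - xi, degree + 1, increasing=True)
        coef, *_ = np.linalg.lstsq(X * sw[:, None], ys[in_win] * sw,
                                   rcond=None)
        fitted[pos] = coef[0]
    out = np.empty(n)
    out[order] = fitted
    return out


def find_variable_genes(cm: CountMatrix, n_top: int = 3000,
                        span: float = 0.3) -> list[str]:
    """Rank genes by standardized variance after VST; return the top ``n_top``.

    Deterministic: ties in standardized variance break by gene-name
    lexicographic order.  If fewer than ``n_top`` genes have nonzero
    variance, all of them are returned with a warning.
    """
    counts = cm.counts.tocsr().astype(float)
    n_genes, n_cells = counts.shape
    mean = np.asarray(counts.mean(axis=1)).ravel()
    sq = counts.copy()
    sq.data **= 2
    ex2 = np.asarray(sq.mean(axis=1)).ravel()
    var = (ex2 - mean**2) * n_cells / max(n_cells - 1, 1)

    expressed = mean > 0
    if int(expressed.sum()) < 10:
        raise ValueError(
            f"only {int(expressed.sum())} expressed genes; need >= 10")
    usable = var > 0
    if int(usable.sum()) < n_top:
        warnings.warn(
            f"only {int(usable.sum())} genes with nonzero variance; "
            f"returning all of them instead of n_top={n_top}")

    fitted_var = np.zeros(n_genes)
    idx = np.flatnonzero(usable)
    trend = _loess_trend(np.log10(mean[idx]), np.log10(var[idx]), span=span)
    fitted_var[idx] = 10.0 ** trend
    sd = np.sqrt(fitted_var)

    # variance of standardized, clipped counts, computed sparsely
    clip = np.sqrt(n_cells)
    std_var = np.zeros(n_genes)
    indptr, data = counts.indptr, counts.data
    m_rep = np.repeat(mean, np.diff(indptr))
    s_rep = np.repeat(np.where(sd > 0, sd, 1.0), np.diff(indptr))
    z_nz = np.clip((data - m_rep) / s_rep, -clip, clip)
    nnz = np.diff(indptr)
    has = nnz > 0
    sum_nz = np.zeros(n_genes)
    sumsq_nz = np.zeros(n_genes)
    sum_nz[has] = np.add.reduceat(z_nz, indptr[:-1][has])
    sumsq_nz[has] = np.add.reduceat(z_nz**2, indptr[:-1][has])
    z0 = np.clip(np.where(sd > 0, -mean / np.where(sd > 0, sd, 1.0), 0.0),
                 -clip, clip)
    n_zero = n_cells - nnz
    total = sum_nz + n_zero * z0
    totalsq = sumsq_nz + n_zero * z0**2
    with np.errstate(invalid="ignore"):
        sv = (totalsq - total**2 / n_cells) / max(n_cells - 1, 1)
    std_var[usable] = sv[usable]

    names = np.array(cm.gene_names)
    cand = np.flatnonzero(usable)
    order = sorted(cand, key=lambda i: (-std_var[i], names[i]))
    return [cm.gene_names[i] for i in order[:min(n_top, len(order))]]


def scale_genes(nm: NormalizedMatrix, gene_subset=None,
                clip: float = 10.0) -> ScaledMatrix:
    """Per-gene z-score across cells, clipped to ±``clip``.

    Zero-variance genes scale to all-zeros rather than NaN.  Input should be
    log-normalized expression.
    """
    genes = list(gene_subset) if gene_subset is not None else list(nm.gene_names)
    index = nm.gene_index()
    missing = [g for g in genes if g not in index]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing[:5]}")
    rows = [index[g] for g in genes]
    X = np.asarray(nm.values[rows, :].todense(), dtype=float)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Z = np.clip((X - mean) / sd_safe, -clip, clip)
    Z[(sd == 0).ravel(), :] = 0.0
    return ScaledMatrix(Z, genes, list(nm.barcodes))
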