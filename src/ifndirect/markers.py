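"""Differential expression by Wilcoxon rank-sum with fold-change filters.

Marker discovery follows the convention of the droplet-scRNA-seq toolchain
this package mirrors: genes are pre-filtered by detection fraction and
log2 fold change, tested with a two-sided Wilcoxon rank-sum test on
log-normalized (never batch-corrected) expression, and adjusted by
Bonferroni over **all** genes considered (the pre-filter count), so adjusted
p-values are comparable across marker tables.  Benjamini-Hochberg is
available by flag.

``wilcoxon_test`` uses midranks for ties and a tie-corrected normal
approximation with continuity correction when both groups have >= 10
observations; smaller problems are solved by exact enumeration of all rank
assignments.
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
import pandas as pd
import scipy.stats as st

from .preprocess import NormalizedMatrix, ScaledMatrix

__all__ = [
    "wilcoxon_test",
    "diff_expr",
    "find_all_markers",
]

#: largest number of rank assignments enumerated exactly
_MAX_ENUM = 200_000


def wilcoxon_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank-sum of x, p).

    Exact enumeration when either group has < 10 observations and the
    combinatorial space is tractable; otherwise the tie-corrected,
    continuity-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n, m = x.size, y.size
    ranks = st.rankdata(np.concatenate([x, y]))
    w_obs = float(ranks[:n].sum())

    small = min(n, m) < 10 and math.comb(n + m, n) <= _MAX_ENUM
    if small:
        mu = n * (n + m + 1) / 2.0
        dev_obs = abs(w_obs - mu)
        total = 0
        extreme = 0
        for combo in itertools.combinations(range(n + m), n):
            total += 1
            if abs(ranks[list(combo)].sum() - mu) >= dev_obs - 1e-9:
                extreme += 1
        return w_obs, extreme / total

    res = st.mannwhitneyu(x, y, alternative="two-sided",
                          method="asymptotic", use_continuity=True)
    return w_obs, float(res.pvalue)


def _log2_fold_change(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """log2((mean expm1 A + 1) / (mean expm1 B + 1)) per gene (rows)."""
    mean_a = np.expm1(A).mean(axis=1)
    mean_b = np.expm1(B).mean(axis=1)
    return np.log2((mean_a + 1.0) / (mean_b + 1.0))


def _adjust(p: np.ndarray, n_tests: int, method: str) -> np.ndarray:
    if method == "bonferroni":
        return np.minimum(1.0, p * n_tests)
    if method == "bh":
        order = np.argsort(p)
        ranked = p[order] * n_tests / (np.arange(len(p)) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(p)
        out[order] = np.minimum(1.0, ranked)
        return out
    raise ValueError(f"unknown adjustment method '{method}'")


def _as_indices(cells, barcodes) -> np.ndarray:
    arr = np.asarray(cells)
    if arr.dtype == bool:
        return np.flatnonzero(arr)
    if arr.dtype.kind in "iu":
        return arr
    lookup = {b: i for i, b in enumerate(barcodes)}
    return np.array([lookup[b] for b in arr])


def diff_expr(nm: NormalizedMatrix, cells_a, cells_b,
              min_pct: float = 0.1, logfc_min: float = 0.25,
              genes=None, correction: str = "bonferroni") -> pd.DataFrame:
    """Wilcoxon differential expression of group A vs group B.

    Positive ``log2_fc`` means higher in A.  ``genes`` restricts the tested
    universe (e.g. a candidate ISG list); the Bonferroni denominator is the
    size of that universe, i.e. the pre-filter gene count.
    """
    if not nm.is_log:
        raise ValueError("diff_expr expects log-normalized input")
    ia = _as_indices(cells_a, nm.barcodes)
    ib = _as_indices(cells_b, nm.barcodes)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("both cell groups must be non-empty")
    if np.intersect1d(ia, ib).size:
        raise ValueError("cell groups overlap")

    if genes is not None:
        index = nm.gene_index()
        missing = [g for g in genes if g not in index]
        if missing:
            warnings.warn(f"{len(missing)} candidate gene(s) absent: "
                          f"{missing[:5]}")
        gene_list = [g for g in genes if g in index]
        rows = np.array([index[g] for g in gene_list])
    else:
        gene_list = list(nm.gene_names)
        rows = np.arange(len(gene_list))
    n_tests = len(gene_list)
    if n_tests == 0:
        raise ValueError("no candidate gene present in the matrix")

    # sparse pass: fold changes and detection fractions without densifying
    SA = nm.values[rows][:, ia]
    SB = nm.values[rows][:, ib]
    expm1_a, expm1_b = SA.copy(), SB.copy()
    expm1_a.data = np.expm1(expm1_a.data)
    expm1_b.data = np.expm1(expm1_b.data)
    mean_a = np.asarray(expm1_a.mean(axis=1)).ravel()
    mean_b = np.asarray(expm1_b.mean(axis=1)).ravel()
    lfc = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    pct_in = np.diff(SA.tocsr().indptr) / max(ia.size, 1)
    pct_out = np.diff(SB.tocsr().indptr) / max(ib.size, 1)

    keep = ((np.maximum(pct_in, pct_out) >= min_pct)
            & (np.abs(lfc) >= logfc_min))
    kept = np.flatnonzero(keep)
    if kept.size == 0:
        return pd.DataFrame(columns=["gene", "log2_fc", "pct_in", "pct_out",
                                     "p_value", "p_adj", "rank"])

    A = np.asarray(SA[kept].todense(), dtype=float)
    B = np.asarray(SB[kept].todense(), dtype=float)
    if min(ia.size, ib.size) >= 10:
        res = st.mannwhitneyu(A, B, axis=1,
                              alternative="two-sided", method="asymptotic",
                              use_continuity=True)
        pvals = np.asarray(res.pvalue, dtype=float)
    else:
        pvals = np.array([wilcoxon_test(A[i], B[i])[1]
                          for i in range(len(kept))])

    table = pd.DataFrame({
        "gene": [gene_list[i] for i in kept],
        "log2_fc": lfc[kept],
        "pct_in": pct_in[kept],
        "pct_out": pct_out[kept],
        "p_value": pvals,
        "p_adj": _adjust(pvals, n_tests, correction),
    })
    table = table.sort_values(
        ["p_value", "log2_fc"], key=lambda s: s if s.name == "p_value"
        else -s.abs()).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def find_all_markers(nm: NormalizedMatrix, clusters, top_n: int = 10,
                     scaled: ScaledMatrix | None = None,
                     min_pct: float = 0.1, logfc_min: float = 0.25,
                     correction: str = "bonferroni"
                     ) -> tuple[dict, pd.DataFrame]:
    """One-vs-rest marker tables per cluster, plus the heatmap input matrix.

    Returns ``(tables, heatmap)``: ``tables`` maps cluster label to its
    marker table; ``heatmap`` has one row per gene in the union of each
    cluster's top ``top_n`` markers and one column per cluster, holding the
    cluster's mean scaled expression (mean log-normalized expression if no
    scaled matrix is supplied).  Singleton clusters are skipped with a
    warning.
    """
    clusters = np.asarray(clusters)
    labels = [c for c in pd.unique(clusters)]
    if len(labels) < 2:
        raise ValueError("need at least 2 clusters")
    tables: dict = {}
    for lab in labels:
        mask = clusters == lab
        if mask.sum() < 2:
            warnings.warn(f"cluster {lab!r} is a singleton; skipped")
            continue
        tables[lab] = diff_expr(nm, mask, ~mask, min_pct=min_pct,
                                logfc_min=logfc_min, correction=correction)

    union: list[str] = []
    for lab, tab in tables.items():
        up = tab[tab["log2_fc"] > 0]
        for g in up.head(top_n)["gene"]:
            if g not in union:
                union.append(g)

    if scaled is not None:
        mat, genes = np.asarray(scaled.values), list(scaled.gene_names)
    else:
        mat, genes = None, list(nm.gene_names)
    gidx = {g: i for i, g in enumerate(genes)}
    heat_rows = [g for g in union if g in gidx]
    heat = np.zeros((len(heat_rows), len(tables)))
    cols = list(tables)
    for jc, lab in enumerate(cols):
        mask = clusters == lab
        for jr, g in enumerate(heat_rows):
            if mat is not None:
                heat[jr, jc] = mat[gidx[g], mask].mean()
            else:
                heat[jr, jc] = float(
                    nm.values[gidx[g], np.flatnonzero(mask)].mean())
    heatmap = pd.DataFrame(heat, index=heat_rows,
                           columns=[str(c) for c in cols])
    return tables, heatmap
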