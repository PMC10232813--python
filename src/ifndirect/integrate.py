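"""Cross-condition dataset integration: CCA embeddings, MNN anchors,
anchor-weighted expression correction.

Datasets from different stimulation conditions share cell-intrinsic subset
structure but differ by treatment-induced programs (e.g. global ISG
induction under dsDNA).  Integration aligns them so clustering groups cells
by subset rather than by condition:

1. **CCA** — the top singular triplets of the cells-by-cells cross-product
   of the two scaled HVG matrices give paired low-dimensional embeddings
   maximizing cross-dataset correlation; rows are L2-normalized.
2. **Anchors** — mutual nearest neighbor cell pairs across the two
   embeddings, scored by shared-neighborhood overlap in the joint space.
3. **Correction** — each query cell is shifted by a Gaussian-kernel weighted
   combination of its nearest anchors' (reference - query) expression
   difference vectors, computed on log-normalized HVG expression.
   Reference cells pass through unchanged.

Anchor filtering in HVG space (the ``k_filter`` parameter) is deliberately
inactive: the parameter is accepted for config compatibility but the
neighborhood re-check is omitted, and anchor scoring uses shared-neighbor
overlap rather than a rank-based score.  Both are intentional, documented
simplifications of the method this stage re-implements.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse.linalg as spla
from sklearn.neighbors import NearestNeighbors

from .preprocess import NormalizedMatrix, ScaledMatrix, scale_genes

logger = logging.getLogger(__name__)

__all__ = [
    "CCAEmbedding",
    "AnchorSet",
    "run_cca",
    "find_anchors",
    "integrate",
    "integrate_many",
    "select_integration_features",
]


@dataclass
class CCAEmbedding:
    """Paired cell embeddings from CCA; rows L2-normalized."""

    cc_ref: np.ndarray       # (n_ref_cells, k)
    cc_query: np.ndarray     # (n_query_cells, k)
    correlations: np.ndarray  # (k,), non-increasing

    @property
    def k(self) -> int:
        return self.cc_ref.shape[1]


@dataclass
class AnchorSet:
    """Mutual-nearest-neighbor cell pairs across two datasets."""

    ref_cells: np.ndarray    # indices into the reference dataset
    query_cells: np.ndarray  # indices into the query dataset
    scores: np.ndarray       # in [0, 1]

    def __len__(self) -> int:
        return len(self.ref_cells)


def _l2_normalize_rows(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    return X / np.maximum(norms, 1e-12)


def run_cca(X_ref: ScaledMatrix, X_query: ScaledMatrix,
            k: int = 30) -> CCAEmbedding:
    """Top-k CCA of two scaled (genes x cells) matrices over shared genes.

    The singular vectors of ``X_ref.T @ X_query`` are the paired cell
    embeddings; the reported canonical correlation of component *i* is the
    cosine between the paired gene-space projections, so identical datasets
    yield correlations of 1.
    """
    if list(X_ref.gene_names) != list(X_query.gene_names):
        raise ValueError("CCA requires identical gene sets in the same order")
    A, B = np.asarray(X_ref.values), np.asarray(X_query.values)
    n_ref, n_query = A.shape[1], B.shape[1]
    if k >= min(n_ref, n_query):
        raise ValueError(f"k={k} must be < min cell count {min(n_ref, n_query)}")
    M = A.T @ B  # cells_ref x cells_query
    v0 = np.linspace(1.0, 2.0, min(M.shape))  # deterministic ARPACK start
    U, s, Vt = spla.svds(M, k=k, v0=v0)
    order = np.argsort(s)[::-1]
    U, s, V = U[:, order], s[order], Vt[order, :].T

    # canonical correlations: cosine of paired gene-space projections
    P, Q = A @ U, B @ V
    denom = np.linalg.norm(P, axis=0) * np.linalg.norm(Q, axis=0)
    corr = np.where(denom > 0, s / denom, 0.0)
    corr = np.clip(corr, -1.0, 1.0)
    csort = np.argsort(corr, kind="stable")[::-1]
    U, V, corr = U[:, csort], V[:, csort], corr[csort]
    # deterministic sign convention: each component's largest-|u| entry is
    # positive, with v flipped jointly (a simultaneous flip preserves the
    # singular structure, so downstream anchors are reproducible)
    flip = np.sign(U[np.argmax(np.abs(U), axis=0), np.arange(U.shape[1])])
    flip[flip == 0] = 1.0
    U = U * flip
    V = V * flip
    return CCAEmbedding(_l2_normalize_rows(U), _l2_normalize_rows(V), corr)


def find_anchors(emb: CCAEmbedding, k_anchor: int = 5, k_filter: int = 200,
                 k_score: int = 30) -> AnchorSet:
    """Mutual nearest neighbors in CC space, scored by joint-kNN overlap.

    ``(i, j)`` is an anchor iff *j* is among the ``k_anchor`` nearest query
    cells to reference cell *i* **and** vice versa (Euclidean distance on the
    L2-normalized embeddings).  Each anchor's score is
    ``|N(i) & N(j)| / k_score`` where neighborhoods (including self) are
    taken in the joint stacked embedding.
    """
    if k_anchor <= 0:
        raise ValueError("k_anchor must be positive")
    R, Q = emb.cc_ref, emb.cc_query
    ka = min(k_anchor, len(Q), len(R))
    nn_q = NearestNeighbors(n_neighbors=ka).fit(Q)
    ref_to_query = nn_q.kneighbors(R, return_distance=False)
    nn_r = NearestNeighbors(n_neighbors=ka).fit(R)
    query_to_ref = nn_r.kneighbors(Q, return_distance=False)

    q_sets = [set(row) for row in query_to_ref]
    pairs = [(i, j) for i in range(len(R)) for j in ref_to_query[i]
             if i in q_sets[j]]
    if not pairs:
        raise ValueError(
            "no anchors: no mutual nearest neighbors between datasets "
            f"(k_anchor={k_anchor}, {len(R)} ref x {len(Q)} query cells)")
    ref_idx = np.array([p[0] for p in pairs])
    query_idx = np.array([p[1] for p in pairs])

    joint = np.vstack([R, Q])
    ks = min(k_score, len(joint))
    nn_joint = NearestNeighbors(n_neighbors=ks).fit(joint)
    hoods = nn_joint.kneighbors(joint, return_distance=False)
    # ensure self-inclusion even under exact ties from duplicated points
    hood_sets = [set(h) | {i} for i, h in enumerate(hoods)]
    scores = np.array([
        len(hood_sets[i] & hood_sets[len(R) + j]) / ks
        for i, j in zip(ref_idx, query_idx)
    ])
    scores = np.clip(scores, 0.0, 1.0)
    logger.info("found %d anchors (mean score %.2f)", len(pairs),
                float(scores.mean()))
    return AnchorSet(ref_idx, query_idx, scores)


def integrate(X_query_log: np.ndarray, anchors: AnchorSet,
              X_ref_log: np.ndarray, k_weight: int = 100,
              embedding: CCAEmbedding | None = None) -> np.ndarray:
    """Correct the query expression matrix toward the reference.

    Both matrices are log-normalized HVG expression, genes x cells on the
    same gene set.  Returns the reference stacked with the corrected query
    (reference columns first, both unchanged in order); reference cells are
    never altered.
    """
    if len(anchors) == 0:
        raise ValueError("anchor set is empty")
    X_ref_log = np.asarray(X_ref_log, dtype=float)
    X_query_log = np.asarray(X_query_log, dtype=float)
    n_query = X_query_log.shape[1]
    # anchor difference vectors, genes x n_anchors
    D = X_ref_log[:, anchors.ref_cells] - X_query_log[:, anchors.query_cells]

    kw = k_weight
    if kw > len(anchors):
        warnings.warn(
            f"k_weight={k_weight} exceeds anchor count {len(anchors)}; "
            "using all anchors")
        kw = len(anchors)

    if embedding is not None:
        coords_cells = embedding.cc_query
        coords_anchors = embedding.cc_query[anchors.query_cells]
    else:  # fall back to expression-space geometry
        coords_cells = X_query_log.T
        coords_anchors = X_query_log[:, anchors.query_cells].T

    nn = NearestNeighbors(n_neighbors=kw).fit(coords_anchors)
    dist, idx = nn.kneighbors(coords_cells)

    corrected = X_query_log.copy()
    sigma = np.maximum(np.median(dist, axis=1), 1e-12)
    kernel = np.exp(-0.5 * (dist / sigma[:, None]) ** 2)
    w = kernel * anchors.scores[idx]
    wsum = w.sum(axis=1)
    flat = wsum <= 0
    if flat.any():  # all-zero anchor scores: fall back to uniform weights
        w[flat] = 1.0
        wsum[flat] = w[flat].sum(axis=1)
    w /= wsum[:, None]
    for c in range(n_query):
        corrected[:, c] += D[:, idx[c]] @ w[c]
    return np.hstack([X_ref_log, corrected])


def select_integration_features(hvg_lists: list[list[str]],
                                n_features: int = 3000,
                                universe: list[str] | None = None
                                ) -> list[str]:
    """Aggregate per-dataset HVG rankings into one shared feature list.

    Genes are scored by their best (minimum) rank across datasets, with the
    number of datasets nominating the gene as the primary key; ties break
    lexicographically for determinism.  If ``universe`` is given, features
    are restricted to it (genes must exist in every dataset).
    """
    from collections import defaultdict

    best_rank: dict[str, int] = defaultdict(lambda: 10**9)
    votes: dict[str, int] = defaultdict(int)
    for ranking in hvg_lists:
        for r, g in enumerate(ranking):
            votes[g] += 1
            best_rank[g] = min(best_rank[g], r)
    genes = list(votes)
    if universe is not None:
        allowed = set(universe)
        genes = [g for g in genes if g in allowed]
    genes.sort(key=lambda g: (-votes[g], best_rank[g], g))
    return genes[:n_features]


def integrate_many(log_mats: list[NormalizedMatrix], features: list[str],
                   k_cca: int = 30, k_anchor: int = 5, k_score: int = 30,
                   k_weight: int = 100
                   ) -> tuple[np.ndarray, list[int], list[AnchorSet]]:
    """Pairwise-integrate >= 2 datasets onto the largest as reference.

    Returns ``(corrected, column_order, anchor_sets)`` where ``corrected`` is
    the features x all-cells matrix with reference cells unchanged, and
    ``column_order`` maps output columns to ``(dataset_index, cell_index)``
    flattened as the datasets' original global order: columns are emitted
    reference-first, then the remaining datasets in input order.
    """
    if len(log_mats) < 2:
        raise ValueError("need at least 2 datasets to integrate")
    dense = []
    scaled = []
    for nm in log_mats:
        if not nm.is_log:
            raise ValueError("integration expects log-normalized input")
        sm = scale_genes(nm, gene_subset=features)
        scaled.append(sm)
        index = nm.gene_index()
        rows = [index[g] for g in features]
        dense.append(np.asarray(nm.values[rows, :].todense(), dtype=float))

    sizes = [m.shape[1] for m in dense]
    ref = int(np.argmax(sizes))  # ties resolve to the first dataset
    others = [i for i in range(len(dense)) if i != ref]

    blocks = [dense[ref]]
    order = [ref]
    anchor_sets: list[AnchorSet] = []
    for i in others:
        k_eff = min(k_cca, min(sizes[ref], sizes[i]) - 1)
        emb = run_cca(scaled[ref], scaled[i], k=k_eff)
        anchors = find_anchors(emb, k_anchor=k_anchor, k_score=k_score)
        both = integrate(dense[i], anchors, dense[ref], k_weight=k_weight,
                         embedding=emb)
        blocks.append(both[:, sizes[ref]:])  # corrected query block only
        order.append(i)
        anchor_sets.append(anchors)
    return np.hstack(blocks), order, anchor_sets
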