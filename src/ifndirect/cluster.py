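"""PCA, SNN graph construction, Louvain clustering, UMAP and cell-cycle
phase assignment.

The clustering recipe is the standard shared-nearest-neighbor pipeline: PCA
on scaled (optionally integrated) expression, a kNN graph in PC space whose
edges are re-weighted by the Jaccard overlap of the two endpoints'
k-neighborhoods (weak edges below 1/15 pruned), and Louvain modularity
optimization with a resolution parameter.  UMAP is quarantined strictly for
visualization: nothing downstream consumes its coordinates, so its
stochasticity can never affect results.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass

import igraph
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .preprocess import NormalizedMatrix
from .scoring import PHASE_PANELS, resolve_panel

__all__ = [
    "PCAResult",
    "SNNGraph",
    "ClusterAssignment",
    "run_pca",
    "build_snn",
    "louvain",
    "run_umap",
    "assign_phase",
]

#: edges with Jaccard weight below this are pruned (kNN-pipeline convention)
SNN_PRUNE = 1.0 / 15.0

#: fixed priority used to break phase-score ties
PHASE_TIE_ORDER = ("S", "G2", "G1")


@dataclass
class PCAResult:
    scores: np.ndarray               # cells x n_pcs
    components: np.ndarray           # n_pcs x genes
    explained_variance: np.ndarray   # n_pcs
    mean: np.ndarray                 # per-gene centering offsets


@dataclass
class SNNGraph:
    """Undirected shared-nearest-neighbor graph with Jaccard edge weights."""

    n_nodes: int
    edges_i: np.ndarray
    edges_j: np.ndarray   # always edges_i < edges_j (no self loops)
    weights: np.ndarray   # in (0, 1]

    @property
    def n_edges(self) -> int:
        return len(self.weights)


@dataclass
class ClusterAssignment:
    labels: np.ndarray   # per-cell ints, contiguous from 0, 0 = largest
    resolution: float
    modularity: float

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0


def run_pca(scaled_values: np.ndarray, n_pcs: int = 30) -> PCAResult:
    """Top principal components of a centered genes x cells matrix.

    Cells are the samples.  A deterministic sign convention is applied: the
    largest-magnitude loading of each component is made positive.
    """
    X = np.asarray(scaled_values, dtype=float).T  # cells x genes
    n_cells, n_genes = X.shape
    if n_pcs >= min(n_cells, n_genes):
        raise ValueError(
            f"n_pcs={n_pcs} must be < min(n_cells, n_genes)="
            f"{min(n_cells, n_genes)}")
    from sklearn.decomposition import PCA

    pca = PCA(n_components=n_pcs, svd_solver="arpack", random_state=0)
    scores = pca.fit_transform(X)
    comps = pca.components_
    flip = np.sign(comps[np.arange(n_pcs),
                         np.argmax(np.abs(comps), axis=1)])
    flip[flip == 0] = 1.0
    return PCAResult(scores * flip, comps * flip[:, None],
                     pca.explained_variance_, pca.mean_)


def _knn_with_self(points: np.ndarray, k: int) -> np.ndarray:
    """k-neighborhoods defined as self plus the k-1 nearest other points."""
    n = len(points)
    nn = NearestNeighbors(n_neighbors=min(k, n)).fit(points)
    idx = nn.kneighbors(points, return_distance=False)
    hoods = np.empty((n, k), dtype=np.int64)
    for i in range(n):
        row = [j for j in idx[i] if j != i][: k - 1]
        # duplicated points can crowd out the self index; re-insert it
        while len(row) < k - 1:
            row.append(i)
        hoods[i] = [i] + row
    return hoods


def build_snn(pc_scores: np.ndarray, k: int = 20,
              prune: float = SNN_PRUNE) -> SNNGraph:
    """SNN graph: Jaccard overlap of k-neighborhoods (self included)."""
    if k <= 0:
        raise ValueError("k must be positive")
    pc_scores = np.asarray(pc_scores, dtype=float)
    n = len(pc_scores)
    if k >= n + 1:
        raise ValueError(f"k={k} too large for {n} cells")
    hoods = _knn_with_self(pc_scores, k)
    rows = np.repeat(np.arange(n), k)
    A = sp.csr_matrix(
        (np.ones(n * k), (rows, hoods.ravel())), shape=(n, n))
    A.data[:] = 1.0  # collapse duplicates from the self re-insertion
    inter = (A @ A.T).tocoo()
    jac = inter.data / (2 * k - inter.data)
    keep = (inter.row < inter.col) & (jac >= prune)
    return SNNGraph(n, inter.row[keep], inter.col[keep], jac[keep])


def louvain(graph: SNNGraph, resolution: float = 0.8,
            seed: int = 0) -> ClusterAssignment:
    """Louvain modularity optimization on the SNN graph.

    Deterministic given ``seed`` (igraph draws its randomness from Python's
    ``random`` module).  Labels are relabeled by decreasing cluster size,
    ties by first occurrence.
    """
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    g = igraph.Graph(n=graph.n_nodes,
                     edges=list(zip(graph.edges_i.tolist(),
                                    graph.edges_j.tolist())))
    weights = graph.weights.tolist()
    state = random.getstate()
    try:
        random.seed(int(seed))
        part = g.community_multilevel(weights=weights, resolution=resolution)
    finally:
        random.setstate(state)
    membership = np.asarray(part.membership)
    modularity = float(g.modularity(membership.tolist(), weights=weights))

    sizes = np.bincount(membership)
    first_seen = np.full(sizes.size, graph.n_nodes)
    for i, m in enumerate(membership):
        first_seen[m] = min(first_seen[m], i)
    order = sorted(range(sizes.size), key=lambda c: (-sizes[c], first_seen[c]))
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[m] for m in membership])
    return ClusterAssignment(labels, resolution, modularity)


def run_umap(pc_scores: np.ndarray, n_neighbors: int = 30,
             min_dist: float = 0.3, seed: int = 0) -> np.ndarray:
    """2-D UMAP embedding for visualization only."""
    pc_scores = np.asarray(pc_scores, dtype=float)
    if len(pc_scores) < n_neighbors:
        raise ValueError(
            f"need >= n_neighbors={n_neighbors} cells, got {len(pc_scores)}")
    if np.allclose(pc_scores, pc_scores[0]):
        warnings.warn("degenerate input (all points identical); "
                      "returning jittered coordinates")
        rng = np.random.default_rng(seed)
        return rng.normal(scale=1e-4, size=(len(pc_scores), 2))
    import umap

    reducer = umap.UMAP(n_neighbors=n_neighbors, min_dist=min_dist,
                        n_components=2, random_state=seed)
    return np.asarray(reducer.fit_transform(pc_scores))


def assign_phase(nm: NormalizedMatrix, phase_panels=None,
                 seed: int = 0) -> tuple[list[str], pd.DataFrame]:
    """Cell-cycle phase call from marker-panel scores.

    Per phase, score = mean log-normalized expression of the panel genes
    minus the mean of a size-matched random control gene set (drawn once
    with a fixed seed from genes outside every panel).  The call is the
    argmax; exact ties resolve in the fixed order S > G2 > G1.
    """
    if not nm.is_log:
        raise ValueError("assign_phase expects log-normalized input")
    panels = phase_panels if phase_panels is not None else PHASE_PANELS
    gene_names = nm.gene_names
    panel_rows: dict[str, list[int]] = {}
    all_panel_rows: set[int] = set()
    for phase, panel in panels.items():
        rows, _missing = resolve_panel(panel, gene_names)
        panel_rows[phase] = rows
        all_panel_rows.update(rows)
    if not any(panel_rows.values()):
        raise ValueError("no phase-panel gene present in the matrix")

    rng = np.random.default_rng(seed)
    candidates = np.array(sorted(set(range(len(gene_names))) - all_panel_rows))
    X = nm.values
    scores = {}
    for phase in panels:
        rows = panel_rows[phase]
        if not rows:
            scores[phase] = np.full(X.shape[1], -np.inf)
            continue
        panel_mean = np.asarray(X[rows, :].mean(axis=0)).ravel()
        ctrl = rng.choice(candidates, size=min(len(rows), len(candidates)),
                          replace=False)
        ctrl_mean = np.asarray(X[ctrl, :].mean(axis=0)).ravel()
        scores[phase] = panel_mean - ctrl_mean

    table = pd.DataFrame(scores, index=nm.barcodes)
    ordered = [p for p in PHASE_TIE_ORDER if p in panels] + \
              [p for p in panels if p not in PHASE_TIE_ORDER]
    mat = np.vstack([scores[p] for p in ordered])
    calls = [ordered[i] for i in np.argmax(mat, axis=0)]
    return calls, table
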