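"""Normalization, embedding, batch centering and graph clustering.

The stage order mirrors the standard scRNA-seq workflow: per-cell count
scaling and log1p transform, highly-variable-gene selection, PCA on the
HVG submatrix, per-batch centering of the principal components, a
symmetrized k-nearest-neighbour graph, and community detection with a
resolution-parameterized modularity objective (Leiden).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .qc import CountMatrix

__all__ = [
    "NormalizedMatrix",
    "Embedding",
    "ClusterAssignment",
    "normalize_log",
    "select_hvg",
    "pca_embed",
    "center_batches",
    "build_knn_graph",
    "detect_communities",
]


@dataclass
class NormalizedMatrix:
    """log1p-transformed, library-size-scaled expression (cells x genes)."""

    values: sp.spmatrix
    scale_target: float
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class Embedding:
    """PCA coordinates with per-component explained variance fractions."""

    coords: np.ndarray
    n_components: int
    variance_explained: np.ndarray


@dataclass
class ClusterAssignment:
    """Per-cell integer labels, dense in 0..n_clusters-1, size-ordered."""

    labels: np.ndarray
    resolution: float
    n_clusters: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(self.labels)
        if not np.array_equal(uniq, np.arange(self.n_clusters)):
            raise ValueError("labels must be dense in 0..n_clusters-1")

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)


def normalize_log(m: CountMatrix, scale_target: float | None = None) -> NormalizedMatrix:
    """Scale each cell to ``scale_target`` total counts, then log1p.

    ``scale_target`` defaults to the median of per-cell total counts.
    Zero counts map to zero, so sparsity is preserved.
    """
    if m.n_cells == 0 or m.n_genes == 0:
        raise ValueError("empty count matrix")
    totals = np.asarray(m.counts.sum(axis=1), dtype=float).ravel()
    if (totals == 0).any():
        bad = m.cell_ids[totals == 0]
        raise ValueError(f"cells with zero total counts: {list(bad[:5])}")
    if scale_target is None:
        scale_target = float(np.median(totals))
    x = sp.csr_matrix(m.counts, dtype=float, copy=True)
    scale = scale_target / totals
    x.data *= np.repeat(scale, np.diff(x.indptr))
    x.data = np.log1p(x.data)
    return NormalizedMatrix(x, float(scale_target), m.gene_ids, m.cell_ids)


def _mean_var(values: sp.spmatrix):
    """Per-gene mean and (population) variance of a sparse matrix."""
    n = values.shape[0]
    mean = np.asarray(values.mean(axis=0)).ravel()
    sq = values.copy()
    sq.data **= 2
    ex2 = np.asarray(sq.mean(axis=0)).ravel()
    var = np.maximum(ex2 - mean**2, 0.0)
    return mean, var * n / max(n - 1, 1)


def select_hvg(nm: NormalizedMatrix, n_top: int, n_bins: int = 20) -> np.ndarray:
    """Indices of the ``n_top`` most variable genes.

    The variability statistic is the variance/mean dispersion of the
    log-scale values, z-scored within 20 equal-frequency mean bins so
    that highly expressed genes do not dominate.  Ties break by gene
    index, so the selection is deterministic.
    """
    if n_top > nm.n_genes:
        raise ValueError("n_top exceeds number of genes")
    mean, var = _mean_var(nm.values)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    # equal-frequency bins over the mean; z-score dispersion within bin.
    # Bins need enough members for a meaningful z-score, so the bin count
    # shrinks on small gene universes (>= ~20 genes per bin).
    n_bins = min(n_bins, max(1, nm.n_genes // 20))
    order = np.argsort(mean, kind="stable")
    bins = np.empty(nm.n_genes, dtype=int)
    bins[order] = np.minimum(
        (np.arange(nm.n_genes) * n_bins) // nm.n_genes, n_bins - 1
    )
    z = np.zeros(nm.n_genes)
    for b in range(n_bins):
        in_bin = bins == b
        if not in_bin.any():
            continue
        d = disp[in_bin]
        sd = d.std()
        z[in_bin] = (d - d.mean()) / sd if sd > 0 else 0.0
    # constant genes can never outrank a non-constant one
    z = np.where(var == 0, -np.inf, z)
    ranked = np.lexsort((np.arange(nm.n_genes), -z))
    return np.sort(ranked[:n_top])


def pca_embed(values, n_components: int) -> Embedding:
    """PCA of a (cells x genes) matrix, genes centered.

    The sign of each component is fixed so that its largest-magnitude
    gene loading is positive, making the embedding deterministic.
    Degenerate inputs with rank below ``n_components`` return the
    available components with a warning.
    """
    x = np.asarray(values.todense() if sp.issparse(values) else values, dtype=float)
    n, p = x.shape
    if n_components > min(n, p):
        raise ValueError("n_components exceeds matrix rank bound")
    xc = x - x.mean(axis=0)
    # full SVD on the desk-scale HVG submatrix is exact and reproducible
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    tol = s[0] * max(n, p) * np.finfo(float).eps if s.size else 0.0
    rank = int((s > tol).sum())
    k = n_components
    if rank < n_components:
        warnings.warn(
            f"requested {n_components} components but rank is {rank}; "
            "returning available components",
            RuntimeWarning,
            stacklevel=2,
        )
        k = max(rank, 1)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(vt[np.arange(k), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    coords = u * s * flip
    total_var = (xc**2).sum()
    var_explained = (s**2) / total_var if total_var > 0 else np.zeros(k)
    return Embedding(coords, k, var_explained)


def center_batches(e: Embedding, batch) -> Embedding:
    """Remove per-batch location shifts in the embedding.

    For each batch and component the batch mean is subtracted and the
    global mean restored; with a single batch this is the identity.
    This removes exactly the location-type batch effects that uniform
    per-gene batch offsets induce in PC space.
    """
    batch = np.asarray(batch)
    if len(batch) != e.coords.shape[0]:
        raise ValueError("batch labels must align with embedding rows")
    levels = pd.unique(batch)
    if len(levels) == 1:
        return e
    coords = e.coords.copy()
    global_mean = coords.mean(axis=0)
    for b in levels:
        mask = batch == b
        coords[mask] += global_mean - coords[mask].mean(axis=0)
    return Embedding(coords, e.n_components, e.variance_explained)


def build_knn_graph(e: Embedding, k: int = 15) -> sp.csr_matrix:
    """Symmetrized kNN graph over Euclidean distances in the embedding.

    Edge (i, j) exists iff j is among i's k nearest neighbours or vice
    versa.  Weights use a Gaussian kernel on distance,
    ``exp(-(d / d_bar)^2)`` with ``d_bar`` the mean kNN distance, so they
    lie in (0, 1] and coincident points get weight 1.  Distance ties are
    broken by cell index.
    """
    n = e.coords.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    nn = NearestNeighbors(n_neighbors=k + 1, algorithm="auto").fit(e.coords)
    dist, idx = nn.kneighbors(e.coords)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    rows = np.repeat(np.arange(n), k)
    cols = idx.ravel()
    d = dist.ravel()
    d_bar = d.mean() if d.size and d.mean() > 0 else 1.0
    w = np.exp(-((d / d_bar) ** 2))
    g = sp.coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr()
    g = g.maximum(g.T)  # undirected: keep an edge if present either way
    g.setdiag(0)
    g.eliminate_zeros()
    return g


def detect_communities(
    graph: sp.spmatrix, resolution: float, seed: int = 0
) -> ClusterAssignment:
    """Leiden partition of a weighted graph.

    Optimizes the resolution-parameterized configuration-null modularity
    (RBConfiguration) objective.  Labels are relabelled by decreasing
    cluster size (ties by original label), and the optimizer is seeded,
    so the assignment is reproducible.
    """
    graph = sp.csr_matrix(graph)
    n = graph.shape[0]
    if n == 0:
        raise ValueError("empty graph")
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    coo = sp.triu(graph, k=1).tocoo()
    g = ig.Graph(
        n=n, edges=list(zip(coo.row.tolist(), coo.col.tolist())), directed=False
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=coo.data.tolist(),
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=2,
    )
    raw = np.asarray(part.membership, dtype=int)
    sizes = np.bincount(raw)
    order = np.lexsort((np.arange(len(sizes)), -sizes))
    relabel = np.empty(len(sizes), dtype=int)
    relabel[order] = np.arange(len(sizes))
    labels = relabel[raw]
    return ClusterAssignment(labels, float(resolution), int(labels.max()) + 1)
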