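"""Normalization, dimensionality reduction and joint clustering.

RNA is log-normalized (counts per 10,000, ``ln1p``) and reduced with PCA on
the top-variance features; ATAC is TF-IDF weighted and reduced with LSI
(truncated SVD), dropping the depth-correlated first component. The two
embeddings are z-scored, concatenated with equal total weight per modality,
and clustered with Leiden community detection on a shared-nearest-neighbor
graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA, TruncatedSVD
from sklearn.neighbors import NearestNeighbors

SCALE_FACTOR = 1e4


@dataclass
class Embedding:
    """Cells x components matrix plus the 1-based component index range used."""

    matrix: np.ndarray
    components: tuple[int, int]  # inclusive 1-based range, e.g. (2, 25)

    def __post_init__(self):
        if not np.isfinite(self.matrix).all():
            raise ValueError("embedding contains non-finite values")


def lognormalize(counts) -> sp.csr_matrix:
    """ln(1 + 1e4 * x / cell_total) per feature x cell matrix."""
    x = sp.csc_matrix(counts, dtype=float)
    totals = np.asarray(x.sum(axis=0)).ravel()
    scale = np.divide(SCALE_FACTOR, totals, out=np.zeros_like(totals), where=totals > 0)
    x = x @ sp.diags(scale)
    x.data = np.log1p(x.data)
    return sp.csr_matrix(x)


def tfidf(atac) -> sp.csr_matrix:
    """ln(1 + TF * IDF * 1e4) with TF = x/cell_total, IDF = n_cells/(1 + detection)."""
    x = sp.csc_matrix(atac, dtype=float)
    totals = np.asarray(x.sum(axis=0)).ravel()
    if (totals == 0).any():
        warnings.warn("cells with zero in-peak counts produce all-zero TF-IDF rows")
    scale = np.divide(1.0, totals, out=np.zeros_like(totals), where=totals > 0)
    tf = x @ sp.diags(scale)
    detection = np.asarray((x > 0).sum(axis=1)).ravel()
    idf = x.shape[1] / (1.0 + detection)
    out = sp.diags(idf) @ tf
    out.data = np.log1p(out.data * SCALE_FACTOR)
    return sp.csr_matrix(out)


def _fix_signs(cell_emb: np.ndarray, loadings: np.ndarray) -> np.ndarray:
    """Force each component's largest-|loading| feature weight positive."""
    idx = np.abs(loadings).argmax(axis=1)
    flips = np.sign(loadings[np.arange(loadings.shape[0]), idx])
    flips = np.where(flips == 0, 1.0, flips)
    return cell_emb * flips[None, :]


def lsi(tfidf_matrix, n_components: int = 25, drop_first: bool = True,
        seed: int = 0) -> Embedding:
    """Truncated SVD of the TF-IDF matrix; component 1 (depth) dropped."""
    x = sp.csr_matrix(tfidf_matrix).T  # cells x peaks
    rank_cap = min(x.shape) - 1
    k = min(n_components, rank_cap)
    if k < n_components:
        warnings.warn(f"rank supports only {k} LSI components")
    svd = TruncatedSVD(n_components=k, random_state=seed, algorithm="arpack")
    emb = svd.fit_transform(x)
    emb = _fix_signs(emb, svd.components_)
    if drop_first:
        return Embedding(matrix=emb[:, 1:], components=(2, k))
    return Embedding(matrix=emb, components=(1, k))


def pca(lognorm_rna, n_components: int = 25, n_top_features: int = 2000,
        seed: int = 0) -> Embedding:
    """PCA of unit-variance-scaled top-variance normalized features."""
    x = sp.csr_matrix(lognorm_rna)
    dense = np.asarray(x.todense())  # features x cells
    var = dense.var(axis=1)
    top = np.argsort(var)[::-1][:min(n_top_features, dense.shape[0])]
    sub = dense[np.sort(top)]
    mean = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    scaled = ((sub - mean) / sd).T  # cells x features
    k = min(n_components, scaled.shape[1], scaled.shape[0] - 1)
    if k < n_components:
        warnings.warn(f"only {k} PCA components available")
    model = PCA(n_components=k, random_state=seed, svd_solver="full")
    emb = model.fit_transform(scaled)
    emb = _fix_signs(emb, model.components_)
    return Embedding(matrix=emb, components=(1, k))


def _zscore(mat: np.ndarray) -> np.ndarray:
    mean = mat.mean(axis=0, keepdims=True)
    sd = mat.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return (mat - mean) / sd


def snn_graph(embedding: np.ndarray, k_neighbors: int = 20) -> sp.csr_matrix:
    """Shared-nearest-neighbor graph with Jaccard edge weights."""
    n = embedding.shape[0]
    if k_neighbors >= n:
        raise ValueError("k_neighbors must be smaller than the number of cells")
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(embedding)
    adj = nn.kneighbors_graph(embedding, mode="connectivity")
    shared = adj @ adj.T
    shared = sp.coo_matrix(shared)
    jac = shared.data / (2 * k_neighbors - shared.data)
    graph = sp.coo_matrix((jac, (shared.row, shared.col)), shape=(n, n))
    graph.setdiag(0)
    graph.eliminate_zeros()
    # prune weak edges as is conventional for SNN clustering
    graph.data[graph.data < 1 / 15] = 0
    graph.eliminate_zeros()
    return sp.csr_matrix(graph)


def joint_cluster(pca_emb: Embedding, lsi_emb: Embedding, k_neighbors: int = 20,
                  resolution: float = 0.1, seed: int = 0) -> np.ndarray:
    """Leiden clustering of the equal-weight joint embedding.

    Each modality's embedding is z-scored per component and scaled so both
    modalities contribute equal total variance to the concatenation.
    """
    a = _zscore(pca_emb.matrix) / np.sqrt(pca_emb.matrix.shape[1])
    b = _zscore(lsi_emb.matrix) / np.sqrt(lsi_emb.matrix.shape[1])
    if a.shape[0] != b.shape[0]:
        raise ValueError("embeddings are not row-aligned")
    joint = np.hstack([a, b])
    graph = snn_graph(joint, k_neighbors=k_neighbors)
    coo = sp.coo_matrix(sp.triu(graph, k=1))
    g = ig.Graph(n=graph.shape[0], edges=list(zip(coo.row, coo.col)),
                 edge_attrs={"weight": coo.data.tolist()})
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=-1,
    )
    labels = np.array(part.membership)
    # stable relabeling: clusters numbered by lowest member cell index
    first = {}
    for i, lab in enumerate(labels):
        first.setdefault(lab, i)
    remap = {lab: rank for rank, (lab, _) in
             enumerate(sorted(first.items(), key=lambda kv: kv[1]))}
    return np.array([remap[lab] for lab in labels])
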