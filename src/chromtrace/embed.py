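"""TF-IDF normalization, iterative LSI embedding, and SNN graph clustering.

The LSI variant: binarize counts, weight by term frequency x
log-inverse-document-frequency, take ln(1 + 1e4 * TF * IDF), then truncated
SVD.  Iterative LSI re-selects variable features from coarse-cluster
pseudobulks over successive rounds, the standard trick for scATAC data where
no informative feature set exists before a first embedding.  Components
highly correlated with sequencing depth are dropped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import svds
from sklearn.neighbors import NearestNeighbors

from .config import ClusterConfig, LSIConfig
from .io import FeatureMatrix

log = logging.getLogger(__name__)


@dataclass
class LSIModel:
    feature_idx: np.ndarray  # indices into the full feature universe
    idf: np.ndarray
    basis: np.ndarray  # selected-features x n_dims, orthonormal columns
    singular_values: np.ndarray
    kept_dims: np.ndarray  # boolean mask after the depth-correlation filter
    n_cells: int

    def project(self, counts: sp.csr_matrix) -> np.ndarray:
        """Project new cells through the stored TF-IDF weights and basis."""
        X = _apply_tfidf(counts[:, self.feature_idx], self.idf)
        return (X @ self.basis)[:, self.kept_dims]


@dataclass
class Embedding:
    coords: np.ndarray
    barcodes: list[str]
    iteration: int = 1

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite embedding coordinates")


def tfidf_transform(matrix: FeatureMatrix | sp.csr_matrix,
                    feature_idx: np.ndarray | None = None
                    ) -> tuple[sp.csr_matrix, np.ndarray]:
    """log-TF-IDF on binarized counts; returns (X, idf).

    TF(i,j) = B(i,j) / rowsum(B, i); IDF(j) = ln(1 + n/(1 + n_j));
    X = ln(1 + 1e4 * TF * IDF).  Zeros stay zero.  Cells with no counts in
    the selected features are flagged with a warning (their rows are zero).
    """
    counts = matrix.counts if isinstance(matrix, FeatureMatrix) else matrix
    if feature_idx is not None:
        counts = counts[:, feature_idx]
    binary = (counts > 0).astype(np.float64).tocsr()
    n_cells = binary.shape[0]
    n_with = np.asarray(binary.sum(axis=0)).ravel()
    idf = np.log(1.0 + n_cells / (1.0 + n_with))
    rowsum = np.asarray(binary.sum(axis=1)).ravel()
    empty = rowsum == 0
    if empty.any():
        warnings.warn(f"{int(empty.sum())} cells have no counts in the "
                      f"selected features; their embedding rows are zero")
        rowsum[empty] = 1.0
    return _apply_tfidf_binary(binary, rowsum, idf), idf


def _apply_tfidf_binary(binary: sp.csr_matrix, rowsum: np.ndarray,
                        idf: np.ndarray) -> sp.csr_matrix:
    X = sp.diags(1.0 / rowsum) @ binary @ sp.diags(idf)
    X = X.tocsr()
    X.data = np.log1p(1e4 * X.data)
    return X


def _apply_tfidf(counts: sp.csr_matrix, idf: np.ndarray) -> sp.csr_matrix:
    binary = (counts > 0).astype(np.float64).tocsr()
    rowsum = np.asarray(binary.sum(axis=1)).ravel()
    rowsum[rowsum == 0] = 1.0
    return _apply_tfidf_binary(binary, rowsum, idf)


def svd_embed(X: sp.csr_matrix, depth: np.ndarray, n_dims: int = 30,
              depth_cor_cutoff: float = 0.75, seed: int = 0
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Truncated SVD; returns (coords U*S on kept dims, basis V, kept mask).

    Dimensions whose cell coordinates correlate with ln(depth) beyond the
    cutoff (|Pearson r| > 0.75 by default) are dropped — those axes track
    sequencing depth, not biology.  Basis column signs are fixed so the
    largest-magnitude entry is positive.
    """
    max_rank = min(X.shape) - 1
    if n_dims > max_rank:
        warnings.warn(f"n_dims {n_dims} exceeds usable rank; using {max_rank}")
        n_dims = max_rank
    v0 = np.random.default_rng(seed).standard_normal(min(X.shape))
    u, s, vt = svds(X.astype(np.float64), k=n_dims, v0=v0)
    order = np.argsort(s)[::-1]
    u, s, vt = u[:, order], s[order], vt[order]
    v = vt.T
    flip = np.sign(v[np.abs(v).argmax(axis=0), np.arange(v.shape[1])])
    flip[flip == 0] = 1.0
    v = v * flip
    u = u * flip
    coords = u * s
    logd = np.log(np.maximum(np.asarray(depth, dtype=float), 1.0))
    kept = np.ones(n_dims, dtype=bool)
    if np.std(logd) > 0:
        for j in range(n_dims):
            cj = coords[:, j]
            if np.std(cj) == 0:
                continue
            r = np.corrcoef(cj, logd)[0, 1]
            if abs(r) > depth_cor_cutoff:
                kept[j] = False
    if not kept.any():  # never drop everything
        kept[np.argmax(s)] = True
    return coords, v, kept


def iterative_lsi(matrix: FeatureMatrix, lsi_cfg: LSIConfig,
                  cluster_cfg: ClusterConfig, seed: int = 0
                  ) -> tuple[LSIModel, Embedding]:
    """Iterative LSI: embed, cluster coarsely, re-select variable features.

    Iteration 1 uses the top-N features by total count; iterations 2..k
    cluster the previous embedding at increasing resolution, build
    per-cluster pseudobulk profiles (counts-per-10k, ln(1+x)), and re-select
    the top-N features by cross-cluster variance.
    """
    lsi_cfg.validate()
    counts = matrix.counts
    depth = matrix.depth
    if depth is None:
        depth = np.asarray(counts.sum(axis=1)).ravel()
    n_features = counts.shape[1]
    n_var = min(lsi_cfg.n_variable_features, n_features)

    totals = np.asarray(counts.sum(axis=0)).ravel()
    feature_idx = np.sort(np.argsort(totals)[::-1][:n_var])

    coords = basis = kept = idf = None
    for iteration in range(1, lsi_cfg.iterations + 1):
        X, idf = tfidf_transform(counts, feature_idx)
        coords, basis, kept = svd_embed(
            X, depth, lsi_cfg.n_dims, lsi_cfg.depth_cor_cutoff, seed=seed)
        if iteration == lsi_cfg.iterations:
            break
        res = lsi_cfg.resolutions[iteration - 1]
        labels = snn_cluster_array(
            coords[:, kept], k_param=cluster_cfg.k_param, resolution=res,
            max_clusters=cluster_cfg.max_clusters, seed=seed)
        n_clusters = len(np.unique(labels))
        if n_clusters < 2:
            log.info("iteration %d: %d cluster(s); feature set carried forward",
                     iteration, n_clusters)
            continue
        pseudo = np.zeros((n_clusters, n_features))
        for ci, cl in enumerate(np.unique(labels)):
            rows = np.flatnonzero(labels == cl)
            pseudo[ci] = np.asarray(counts[rows].sum(axis=0)).ravel()
        lib = pseudo.sum(axis=1, keepdims=True)
        lib[lib == 0] = 1.0
        pseudo = np.log1p(1e4 * pseudo / lib)
        variance = pseudo.var(axis=0)
        feature_idx = np.sort(np.argsort(variance)[::-1][:n_var])

    model = LSIModel(feature_idx=feature_idx, idf=idf, basis=basis,
                     singular_values=np.linalg.norm(coords, axis=0),
                     kept_dims=kept, n_cells=counts.shape[0])
    emb = Embedding(coords[:, kept], list(matrix.barcodes),
                    iteration=lsi_cfg.iterations)
    return model, emb


def batch_adjust(embedding: Embedding, batches: pd.Series | np.ndarray
                 ) -> Embedding:
    """Per-dimension location/scale matching across batches.

    Each batch is centered to the pooled mean and rescaled to the pooled
    standard deviation, dimension by dimension.  Identity for one batch;
    batches with < 2 cells are centered only.
    """
    labels = np.asarray(batches)
    uniq = np.unique(labels)
    coords = embedding.coords.copy()
    if len(uniq) <= 1:
        return Embedding(coords, embedding.barcodes, embedding.iteration)
    pooled_mean = coords.mean(axis=0)
    pooled_sd = coords.std(axis=0)
    for b in uniq:
        rows = np.flatnonzero(labels == b)
        block = coords[rows]
        bmean = block.mean(axis=0)
        if rows.size >= 2:
            bsd = block.std(axis=0)
            scale = np.where(bsd > 0, pooled_sd / np.where(bsd > 0, bsd, 1.0), 1.0)
        else:
            scale = 1.0
        coords[rows] = (block - bmean) * scale + pooled_mean
    return Embedding(coords, embedding.barcodes, embedding.iteration)


def snn_cluster_array(coords: np.ndarray, k_param: int = 30,
                      resolution: float = 1.0, max_clusters: int = 60,
                      snn_prune: float = 1.0 / 15.0, seed: int = 0
                      ) -> np.ndarray:
    """Shared-nearest-neighbor Leiden clustering; labels 1..C, C <= max."""
    n = coords.shape[0]
    if k_param >= n:
        raise ValueError(f"k_param ({k_param}) must be < n_cells ({n})")
    nn = NearestNeighbors(n_neighbors=k_param).fit(coords)
    _, idx = nn.kneighbors(coords)  # includes self at position 0
    # neighbor-set membership matrix -> SNN Jaccard weights on kNN edges
    member = sp.coo_matrix(
        (np.ones(idx.size), (np.repeat(np.arange(n), k_param), idx.ravel())),
        shape=(n, n)).tocsr()
    shared = member @ member.T  # |N_i & N_j| restricted below to kNN edges
    knn_mask = member.maximum(member.T)
    inter = shared.multiply(knn_mask)
    inter = inter.tocoo()
    jac = inter.data / (2 * k_param - inter.data)
    keep = (jac >= snn_prune) & (inter.row != inter.col)
    edges = np.stack([inter.row[keep], inter.col[keep]], axis=1)
    weights = jac[keep]
    # undirected: deduplicate symmetric pairs
    lo = edges.min(axis=1)
    hi = edges.max(axis=1)
    key = lo.astype(np.int64) * n + hi
    _, first = np.unique(key, return_index=True)
    g = igraph.Graph(n=n, edges=[(int(lo[i]), int(hi[i])) for i in first])
    g.es["weight"] = [float(weights[i]) for i in first]
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights="weight", resolution_parameter=resolution, seed=int(seed))
    labels = np.asarray(part.membership) + 1
    labels = _merge_small_clusters(coords, labels, max_clusters)
    return labels


def _merge_small_clusters(coords: np.ndarray, labels: np.ndarray,
                          max_clusters: int) -> np.ndarray:
    """Merge the smallest cluster into its nearest-centroid cluster until C<=max."""
    labels = labels.copy()
    while True:
        uniq, counts = np.unique(labels, return_counts=True)
        if len(uniq) <= max_clusters:
            break
        smallest = uniq[np.argmin(counts)]
        centroids = {c: coords[labels == c].mean(axis=0) for c in uniq}
        src = centroids[smallest]
        best, best_d = None, np.inf
        for c in uniq:
            if c == smallest:
                continue
            d = float(np.sum((centroids[c] - src) ** 2))
            if d < best_d:
                best, best_d = c, d
        labels[labels == smallest] = best
    # relabel compactly as 1..C
    uniq = np.unique(labels)
    remap = {c: i + 1 for i, c in enumerate(uniq)}
    return np.array([remap[c] for c in labels])


def snn_cluster(embedding: Embedding, cfg: ClusterConfig, seed: int = 0
                ) -> pd.Series:
    labels = snn_cluster_array(
        embedding.coords, k_param=cfg.k_param, resolution=cfg.resolution,
        max_clusters=cfg.max_clusters, snn_prune=cfg.snn_prune, seed=seed)
    return pd.Series(labels, index=embedding.barcodes, name="cluster")
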