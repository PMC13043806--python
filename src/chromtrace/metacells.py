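"""Metacell identification via kernel archetypal analysis.

Cells are grouped into a fixed number of metacells by factorizing a
cell-cell affinity kernel M as M ~ M @ B @ A with column-stochastic weight
matrices: each archetype is a convex combination of cells (columns of B)
and each cell is a convex mixture of archetypes (columns of A).  Archetypes
are initialized from waypoints — extrema of the leading eigenvectors of the
degree-normalized kernel, topped up by greedy max-min selection — and fitted
by Frank-Wolfe alternating minimization of ||M - M B A||_F^2, which keeps
both matrices on the simplex and the objective non-increasing.  Cells take
the argmax of their archetype weights as a hard metacell assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import eigsh
from sklearn.neighbors import NearestNeighbors

from .io import FeatureMatrix

log = logging.getLogger(__name__)


def build_kernel(coords: np.ndarray, k: int = 15) -> sp.csr_matrix:
    """Adaptive-bandwidth Gaussian kernel on the union of kNN edges.

    sigma_i = distance to the ceil(k/3)-th neighbor; affinity
    m_ij = exp(-d_ij^2 / (sigma_i * sigma_j)), symmetrized by maximum.
    The diagonal is 1, the row-wise maximum.
    """
    n = coords.shape[0]
    if k >= n:
        raise ValueError(f"kernel k ({k}) must be < n_cells ({n})")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    dist, idx = nn.kneighbors(coords)  # column 0 is self
    band_col = int(np.ceil(k / 3))
    sigma = dist[:, band_col].copy()
    sigma[sigma <= 0] = np.finfo(float).tiny ** 0.25
    rows = np.repeat(np.arange(n), k + 1)
    cols = idx.ravel()
    d2 = (dist.ravel()) ** 2
    vals = np.exp(-d2 / (sigma[rows] * sigma[cols]))
    M = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    M = M.maximum(M.T)
    M.setdiag(1.0)
    return M.tocsr()


def init_waypoints(kernel: sp.csr_matrix, coords: np.ndarray,
                   n_archetypes: int = 90, n_waypoint_eigs: int = 10,
                   seed: int = 0) -> np.ndarray:
    """Waypoint initialization: eigenvector extrema + greedy max-min fill.

    Takes the top eigenvectors of the symmetrically degree-normalized kernel,
    collects the argmax and argmin cell of each (deduplicated, order
    preserved), then fills remaining archetype slots by greedy max-min
    Euclidean distance in the embedding.  Deterministic given the seed (used
    only when no waypoint exists to start the greedy fill).
    """
    n = kernel.shape[0]
    if n_archetypes > n:
        raise ValueError(f"n_archetypes ({n_archetypes}) > n_cells ({n})")
    chosen: list[int] = []
    if n_waypoint_eigs > 0 and n > 2:
        deg = np.asarray(kernel.sum(axis=1)).ravel()
        deg[deg <= 0] = 1.0
        Dn = sp.diags(1.0 / np.sqrt(deg))
        K = Dn @ kernel @ Dn
        k_eig = min(n_waypoint_eigs, n - 1)
        from scipy.sparse.linalg import ArpackNoConvergence
        try:
            _, vecs = eigsh(K, k=k_eig, which="LA", tol=1e-8,
                            v0=np.full(n, 1.0 / np.sqrt(n)))
        except ArpackNoConvergence as err:
            # waypoints only need approximate extrema; partially converged
            # eigenvectors (or a looser solve) are ample
            if err.eigenvectors is not None and err.eigenvectors.shape[1]:
                vecs = err.eigenvectors
                log.warning("eigendecomposition partially converged "
                            "(%d/%d eigenvectors); using the converged ones",
                            vecs.shape[1], k_eig)
            else:
                _, vecs = eigsh(K, k=k_eig, which="LA", tol=1e-4,
                                maxiter=50 * n,
                                v0=np.full(n, 1.0 / np.sqrt(n)))
        for j in range(vecs.shape[1] - 1, -1, -1):  # leading first
            for cand in (int(np.argmax(vecs[:, j])), int(np.argmin(vecs[:, j]))):
                if cand not in chosen and len(chosen) < n_archetypes:
                    chosen.append(cand)
    if not chosen:
        rng = np.random.default_rng(seed)
        chosen.append(int(rng.integers(n)))
    # greedy max-min fill in embedding space; ties break to the lowest index
    min_d = np.min(
        np.stack([np.sum((coords - coords[c]) ** 2, axis=1) for c in chosen]),
        axis=0)
    while len(chosen) < n_archetypes:
        min_d[chosen] = -1.0
        nxt = int(np.argmax(min_d))
        chosen.append(nxt)
        d = np.sum((coords - coords[nxt]) ** 2, axis=1)
        min_d = np.minimum(min_d, d)
    return np.array(chosen[:n_archetypes], dtype=int)


@dataclass
class ArchetypeModel:
    A: np.ndarray  # n_archetypes x n_cells, columns on the simplex
    B: np.ndarray  # n_cells x n_archetypes, columns on the simplex
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = False
    iterations: int = 0

    def check_constraints(self, tol: float = 1e-8) -> None:
        for name, mat in (("A", self.A), ("B", self.B)):
            if (mat < -tol).any():
                raise AssertionError(f"{name} has negative entries")
            if not np.allclose(mat.sum(axis=0), 1.0, atol=tol):
                raise AssertionError(f"{name} columns do not sum to 1")


def _frank_wolfe_A(K: np.ndarray, A: np.ndarray, B: np.ndarray,
                   n_steps: int) -> np.ndarray:
    """FW steps on f(A) = ||M - M B A||^2 with column-simplex constraint."""
    BtK = B.T @ K  # k x n
    BtKB = BtK @ B  # k x k
    for _ in range(n_steps):
        G = 2.0 * (BtKB @ A - BtK)  # gradient, k x n
        S = np.zeros_like(A)
        S[np.argmin(G, axis=0), np.arange(A.shape[1])] = 1.0
        D = S - A
        lin = np.sum(G * D)
        quad = np.sum(D * (BtKB @ D))
        if quad <= 0 or not np.isfinite(quad):
            gamma = 1.0 if lin < 0 else 0.0
        else:
            gamma = np.clip(-lin / (2.0 * quad), 0.0, 1.0)
        if gamma == 0.0:
            break
        A = A + gamma * D
    return A


def _frank_wolfe_B(K: np.ndarray, A: np.ndarray, B: np.ndarray,
                   n_steps: int) -> np.ndarray:
    """FW steps on f(B) = ||M - M B A||^2 with column-simplex constraint."""
    AAt = A @ A.T  # k x k
    KAt = K @ A.T  # n x k
    for _ in range(n_steps):
        G = 2.0 * (K @ B @ AAt - KAt)  # n x k
        S = np.zeros_like(B)
        S[np.argmin(G, axis=0), np.arange(B.shape[1])] = 1.0
        D = S - B
        lin = np.sum(G * D)
        KD = K @ D
        quad = np.sum((D @ AAt) * KD)
        if quad <= 0 or not np.isfinite(quad):
            gamma = 1.0 if lin < 0 else 0.0
        else:
            gamma = np.clip(-lin / (2.0 * quad), 0.0, 1.0)
        if gamma == 0.0:
            break
        B = B + gamma * D
    return B


def _objective(trK: float, K: np.ndarray, A: np.ndarray, B: np.ndarray
               ) -> float:
    # ||M - MBA||^2 = tr(K) - 2 tr(A^T B^T K) + tr(A^T B^T K B A)
    BtK = B.T @ K
    cross = float(np.sum(BtK * A))  # tr(A^T B^T K) with A k x n
    BtKB = BtK @ B
    quad = float(np.sum((BtKB @ A) * A))
    return trK - 2.0 * cross + quad


def fit_archetypes(kernel: sp.csr_matrix, init: np.ndarray,
                   epsilon: float = 1e-5, min_iter: int = 10,
                   max_iter: int = 50, refine_iter: int = 5,
                   inner_steps: int = 20) -> ArchetypeModel:
    """Alternating Frank-Wolfe minimization of ||M - M B A||_F^2.

    B starts one-hot at the initial archetype cells, A uniform.  Each outer
    iteration runs ``inner_steps`` FW steps for A then for B.  Stops when
    the relative objective change drops below ``epsilon`` after at least
    ``min_iter`` iterations (or at ``max_iter``), then performs
    ``refine_iter`` further refinement iterations.
    """
    n = kernel.shape[0]
    k = len(init)
    K = np.asarray((kernel.T @ kernel).todense(), dtype=np.float64)
    trK = float(np.trace(K))
    B = np.zeros((n, k))
    B[init, np.arange(k)] = 1.0
    A = np.full((k, n), 1.0 / k)
    obj_prev = _objective(trK, K, A, B)
    trace = [obj_prev]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        A = _frank_wolfe_A(K, A, B, inner_steps)
        B = _frank_wolfe_B(K, A, B, inner_steps)
        obj = _objective(trK, K, A, B)
        if not np.isfinite(obj):
            raise RuntimeError(
                f"archetype objective became non-finite at iteration {it} "
                f"(previous value {obj_prev:.6g})")
        trace.append(obj)
        rel = abs(obj_prev - obj) / max(abs(obj_prev), 1e-300)
        obj_prev = obj
        if it >= min_iter and rel < epsilon:
            converged = True
            break
    for _ in range(refine_iter):
        A = _frank_wolfe_A(K, A, B, inner_steps)
        B = _frank_wolfe_B(K, A, B, inner_steps)
        trace.append(_objective(trK, K, A, B))
    model = ArchetypeModel(A=A, B=B, objective_trace=trace,
                           converged=converged, iterations=it)
    model.check_constraints()
    return model


@dataclass
class MetacellAssignment:
    cells: pd.DataFrame  # barcode, metacell (1..n_archetypes)
    profiles: pd.DataFrame  # metacell x feature aggregated counts
    empty_metacells: list[int]

    @property
    def n_assigned_ids(self) -> int:
        return int(self.cells["metacell"].nunique())


def assign_metacells(model: ArchetypeModel, matrix: FeatureMatrix
                     ) -> MetacellAssignment:
    """Hard assignment: argmax of each cell's archetype weights (ties to the
    lowest id); aggregated profiles sum member cells' counts per metacell."""
    k, n = model.A.shape
    if n != matrix.shape[0]:
        raise ValueError("model and matrix cell counts differ")
    ids = np.argmax(model.A, axis=0) + 1  # argmax takes the first maximum
    cells = pd.DataFrame({"barcode": matrix.barcodes, "metacell": ids})
    prof = np.zeros((k, matrix.shape[1]))
    for m in range(1, k + 1):
        rows = np.flatnonzero(ids == m)
        if rows.size:
            prof[m - 1] = np.asarray(matrix.counts[rows].sum(axis=0)).ravel()
    empty = [m for m in range(1, k + 1) if (ids == m).sum() == 0]
    if empty:
        log.warning("%d metacell ids are empty: %s", len(empty), empty)
    profiles = pd.DataFrame(prof, index=np.arange(1, k + 1),
                            columns=matrix.features)
    return MetacellAssignment(cells, profiles, empty)
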