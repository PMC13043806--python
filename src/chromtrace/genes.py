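"""Gene activity scores from accessibility near gene bodies.

A gene's activity score sums feature counts weighted by exponential decay of
the distance between the feature midpoint and the gene body (extended
upstream of the TSS), then normalizes per cell to 10k and ln(1+x) so scores
are depth-comparable across tissues.  Neighbor-mean imputation smooths the
sparse raw scores; a peak-to-gene annotation table links marker peaks to
TSS-proximal genes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .io import FeatureMatrix

log = logging.getLogger(__name__)


def _extended_body(row) -> tuple[int, int]:
    return row.ext_start, row.ext_end


def gene_scores(matrix: FeatureMatrix, genes: pd.DataFrame,
                decay_bp: float = 5000.0, max_dist_bp: float = 100000.0,
                upstream_ext_bp: int = 5000,
                normalize: bool = True) -> FeatureMatrix:
    """Distance-weighted gene activity from a tile or peak matrix.

    Weight w = exp(-d / decay_bp) with d the distance from the feature
    midpoint to the nearest edge of the gene body extended ``upstream_ext_bp``
    on the TSS side (w = 1 inside, w = 0 beyond ``max_dist_bp``).
    """
    intervals = matrix.feature_intervals()
    f_chrom = np.array([iv.chrom for iv in intervals])
    f_mid = np.array([iv.midpoint for iv in intervals], dtype=np.int64)

    g = genes.copy()
    plus = g["strand"] == "+"
    g["ext_start"] = np.where(plus, g["start"] - upstream_ext_bp, g["start"])
    g["ext_end"] = np.where(plus, g["end"], g["end"] + upstream_ext_bp)

    rows_i: list[np.ndarray] = []
    rows_j: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    for j, grow in enumerate(g.itertuples()):
        on = f_chrom == grow.chrom
        mid = f_mid[on]
        d = np.maximum.reduce([
            grow.ext_start - mid, mid - (grow.ext_end - 1),
            np.zeros(mid.size, dtype=np.int64)])
        w = np.exp(-d / decay_bp)
        w[d > max_dist_bp] = 0.0
        nz = w > 0
        if not nz.any():
            log.info("gene %s has no features within range", grow.name)
            continue
        rows_i.append(np.flatnonzero(on)[nz])
        rows_j.append(np.full(int(nz.sum()), j))
        vals.append(w[nz])
    n_feat, n_genes = len(intervals), len(g)
    if rows_i:
        W = sp.coo_matrix(
            (np.concatenate(vals),
             (np.concatenate(rows_i), np.concatenate(rows_j))),
            shape=(n_feat, n_genes)).tocsr()
    else:
        W = sp.csr_matrix((n_feat, n_genes))
    raw = matrix.counts @ W
    raw = np.asarray(raw.todense()) if sp.issparse(raw) else np.asarray(raw)
    if normalize:
        lib = raw.sum(axis=1, keepdims=True)
        lib[lib == 0] = 1.0
        raw = np.log1p(1e4 * raw / lib)
    return FeatureMatrix(sp.csr_matrix(raw), list(matrix.barcodes),
                         list(g["name"]), "gene_score", matrix.depth)


def impute_scores(scores: FeatureMatrix, coords: np.ndarray, k: int = 15
                  ) -> FeatureMatrix:
    """Replace each cell's scores with the mean over its k nearest embedding
    neighbors (self included); one round of row-stochastic smoothing."""
    n = scores.shape[0]
    if coords.shape[0] != n:
        raise ValueError("embedding rows do not align with score rows")
    if k > n:
        log.warning("impute k=%d clamped to n_cells=%d", k, n)
        k = n
    nn = NearestNeighbors(n_neighbors=k).fit(coords)
    _, idx = nn.kneighbors(coords)
    S = sp.coo_matrix(
        (np.full(idx.size, 1.0 / k), (np.repeat(np.arange(n), k), idx.ravel())),
        shape=(n, n)).tocsr()
    smoothed = S @ scores.counts
    return FeatureMatrix(sp.csr_matrix(smoothed), list(scores.barcodes),
                         list(scores.features), "gene_score", scores.depth)


def annotate_peaks_to_genes(peaks: pd.DataFrame, genes: pd.DataFrame,
                            window_bp: int = 3000) -> pd.DataFrame:
    """Assign each peak to genes whose TSS lies within +/-window of the peak.

    A peak [s, e) claims every TSS in [s - window, e + window); distance is
    signed bp from the TSS to the nearest peak edge, 0 if the TSS overlaps.
    """
    rows = []
    for prow in peaks.itertuples():
        near = genes[(genes["chrom"] == prow.chrom)
                     & (genes["tss"] >= prow.start - window_bp)
                     & (genes["tss"] < prow.end + window_bp)]
        for grow in near.itertuples():
            if prow.start <= grow.tss < prow.end:
                dist = 0
            elif grow.tss < prow.start:
                dist = grow.tss - prow.start
            else:
                dist = grow.tss - (prow.end - 1)
            rows.append((prow.peak_id, grow.name, dist))
    return pd.DataFrame(rows, columns=["peak_id", "gene", "distance"])
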