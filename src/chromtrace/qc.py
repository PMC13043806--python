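"""Per-barcode quality control.

Three metrics: total fragment depth, TSS enrichment (insertion density at
transcription start sites over distal flanks), and a doublet enrichment
score from synthetic-doublet k-nearest-neighbor voting in the LSI embedding.
Cells are retained when depth >= 1000 and TSS enrichment >= 4 (boundaries
inclusive); doublets are scored but not removed unless a threshold is set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .config import PipelineConfig, QCConfig
from .features import Genome, insertion_positions, genome_offsets
from .io import FeatureMatrix


def insertion_profile(frags: pd.DataFrame, tss: pd.DataFrame, genome: Genome,
                      window_bp: int = 2000,
                      per_barcode: bool = False):
    """Insertion counts by position relative to TSS, strand-oriented.

    ``tss`` needs columns chrom/tss/strand.  Positions run -window..+window
    (downstream of the TSS is positive).  Returns a length 2*window+1 vector,
    or a DataFrame of per-barcode profiles when ``per_barcode`` is set.
    A TSS whose window spans several gene windows counts each insertion once
    per overlapping window (profiles are additive over TSS entries).
    """
    if len(tss) == 0:
        raise ValueError("empty TSS list")
    names, offsets = genome_offsets(genome)
    cmap = {c: i for i, c in enumerate(names)}
    tci = tss["chrom"].map(cmap).to_numpy(dtype=np.int64)
    tpos = tss["tss"].to_numpy() + offsets[tci]
    tstrand = (tss["strand"] == "-").to_numpy()
    torder = np.argsort(tpos)
    tpos_s, tneg_s = tpos[torder], tstrand[torder]

    pos, rows = insertion_positions(frags, genome, weighted=True)
    width = 2 * window_bp + 1
    # each insertion can fall in the window of the nearest few TSS; windows are
    # far sparser than the genome, so scan candidate TSS indices around each hit
    lo = np.searchsorted(tpos_s, pos - window_bp, side="left")
    hi = np.searchsorted(tpos_s, pos + window_bp, side="right")
    n_hits = hi - lo
    hit_mask = n_hits > 0
    out_rows: list[np.ndarray] = []
    out_rel: list[np.ndarray] = []
    max_span = int(n_hits.max()) if n_hits.size else 0
    for k in range(max_span):
        sel = np.flatnonzero(n_hits > k)
        ti = lo[sel] + k
        rel = pos[sel] - tpos_s[ti]
        rel = np.where(tneg_s[ti], -rel, rel)
        out_rows.append(rows[sel])
        out_rel.append(rel + window_bp)
    if out_rel:
        rel_all = np.concatenate(out_rel)
        rows_all = np.concatenate(out_rows)
    else:
        rel_all = np.zeros(0, dtype=np.int64)
        rows_all = np.zeros(0, dtype=np.int64)

    if not per_barcode:
        return np.bincount(rel_all, minlength=width).astype(float)
    barcodes = pd.unique(frags["barcode"])
    bmap = {b: i for i, b in enumerate(barcodes)}
    bc = frags["barcode"].map(bmap).to_numpy()
    mat = sp.coo_matrix(
        (np.ones(rel_all.size), (bc[rows_all], rel_all)),
        shape=(len(barcodes), width),
    ).toarray()
    return pd.DataFrame(mat, index=barcodes,
                        columns=np.arange(-window_bp, window_bp + 1))


def tss_enrichment_score(profile: np.ndarray, qc: QCConfig | None = None
                         ) -> float:
    """Center-over-flank ratio of an insertion profile.

    Mean count over relative positions within +/-50 bp of the TSS divided by
    the mean over the outermost 100 bp of each flank (guarded by epsilon).
    """
    qc = qc or QCConfig()
    profile = np.asarray(profile, dtype=float)
    window = (len(profile) - 1) // 2
    c = qc.tss_center_bp
    center = profile[window - c: window + c + 1].mean()
    f = qc.tss_flank_bp
    flank = np.concatenate([profile[:f], profile[-f:]]).mean()
    return float(center / max(flank, qc.tss_eps))


def qc_metrics(frags: pd.DataFrame, tss: pd.DataFrame, genome: Genome,
               config: PipelineConfig) -> pd.DataFrame:
    """Per-barcode depth + TSS enrichment + pass flag."""
    profiles = insertion_profile(frags, tss, genome,
                                 window_bp=config.qc.tss_window_bp,
                                 per_barcode=True)
    depth = frags.groupby("barcode", sort=False)["count"].sum()
    barcodes = list(profiles.index)
    scores = np.array([
        tss_enrichment_score(profiles.loc[b].to_numpy(), config.qc)
        for b in barcodes
    ])
    out = pd.DataFrame({
        "barcode": barcodes,
        "n_fragments": depth.reindex(barcodes).fillna(0).astype(int).to_numpy(),
        "tss_enrichment": scores,
    })
    out["pass_filter"] = (
        (out["n_fragments"] >= config.qc.min_fragments)
        & (out["tss_enrichment"] >= config.qc.min_tss_enrichment)
    )
    return out


def doublet_enrichment(matrix: FeatureMatrix, lsi_model,
                       k: int = 10, n_synthetic: int | None = None,
                       seed: int = 0) -> pd.Series:
    """Synthetic-doublet KNN enrichment score per cell.

    Synthesizes barcodes by summing random distinct cell pairs' counts,
    projects real + synthetic cells into the fitted LSI basis, and scores
    each real cell by the fraction of synthetic barcodes among its k nearest
    neighbors, normalized by the synthetic prior.
    """
    n_real = matrix.shape[0]
    if n_synthetic is None:
        n_synthetic = n_real
    rng = np.random.default_rng(seed)
    if n_synthetic == 0:
        return pd.Series(np.zeros(n_real), index=matrix.barcodes)
    if k >= n_real + n_synthetic:
        raise ValueError("k must be smaller than the pooled cell count")
    a = rng.integers(0, n_real, size=n_synthetic)
    shift = rng.integers(1, n_real, size=n_synthetic)
    b = (a + shift) % n_real  # distinct partner
    synth = matrix.counts[a] + matrix.counts[b]
    real_emb = lsi_model.project(matrix.counts)
    synth_emb = lsi_model.project(sp.csr_matrix(synth))
    pooled = np.vstack([real_emb, synth_emb])
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pooled)
    _, idx = nn.kneighbors(pooled[:n_real])
    neigh = idx[:, 1:]  # drop self
    frac = (neigh >= n_real).mean(axis=1)
    prior = n_synthetic / (n_synthetic + n_real)
    return pd.Series(frac / prior, index=matrix.barcodes)


def filter_cells(metrics: pd.DataFrame, config: PipelineConfig) -> list[str]:
    """Barcodes retained under the depth/TSS rule (and optional doublet cut)."""
    keep = (
        (metrics["n_fragments"] >= config.qc.min_fragments)
        & (metrics["tss_enrichment"] >= config.qc.min_tss_enrichment)
    )
    if config.qc.doublet_threshold is not None and "doublet_enrichment" in metrics:
        keep &= metrics["doublet_enrichment"] < config.qc.doublet_threshold
    return metrics.loc[keep, "barcode"].tolist()
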