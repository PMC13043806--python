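"""Tile matrix, pseudobulk peak calling, and the capped peak matrix.

A single counting convention runs through the whole pipeline: every fragment
contributes two Tn5 insertion sites, ``start`` and ``end - 1``, and features
(tiles, peaks, TSS windows, footprint windows) count insertions, not
fragment overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .io import FeatureMatrix, GenomicInterval

Genome = list[tuple[str, int]]


def genome_offsets(genome: Genome) -> tuple[list[str], np.ndarray]:
    names = [c for c, _ in genome]
    lengths = np.array([l for _, l in genome], dtype=np.int64)
    return names, np.concatenate([[0], np.cumsum(lengths)])


def insertion_positions(frags: pd.DataFrame, genome: Genome,
                        weighted: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Global-coordinate insertion sites and their source row indices.

    Returns (positions, row_index) with two entries per fragment record.
    ``weighted`` repeats insertions by the record's duplicate count.
    """
    names, offsets = genome_offsets(genome)
    cmap = {c: i for i, c in enumerate(names)}
    codes = frags["chrom"].map(cmap)
    if codes.isna().any():
        bad = frags["chrom"][codes.isna()].iloc[0]
        raise KeyError(f"fragment chromosome {bad!r} not in genome")
    off = offsets[codes.to_numpy(dtype=np.int64)]
    starts = frags["start"].to_numpy() + off
    ends = frags["end"].to_numpy() - 1 + off
    pos = np.concatenate([starts, ends])
    rows = np.concatenate([np.arange(len(frags))] * 2)
    if weighted:
        rep = np.concatenate([frags["count"].to_numpy()] * 2)
        pos = np.repeat(pos, rep)
        rows = np.repeat(rows, rep)
    return pos, rows


def make_tile_matrix(frags: pd.DataFrame, genome: Genome,
                     tile_bp: int = 5000,
                     barcodes: list[str] | None = None) -> FeatureMatrix:
    """Cells x 5-kb-tile insertion counts; the last partial tile is included."""
    if barcodes is not None:
        frags = frags[frags["barcode"].isin(set(barcodes))].reset_index(drop=True)
    names, offsets = genome_offsets(genome)
    lengths = np.diff(offsets)
    n_tiles_per = (lengths + tile_bp - 1) // tile_bp
    tile_offsets = np.concatenate([[0], np.cumsum(n_tiles_per)])

    labels = []
    for ci, (chrom, length) in enumerate(genome):
        for k in range(n_tiles_per[ci]):
            labels.append(GenomicInterval(
                chrom, k * tile_bp, min((k + 1) * tile_bp, length)).label())

    pos, rows = insertion_positions(frags, genome, weighted=True)
    ci = np.searchsorted(offsets, pos, side="right") - 1
    local = pos - offsets[ci]
    tile_idx = tile_offsets[ci] + local // tile_bp

    if barcodes is None:
        barcodes = sorted(frags["barcode"].unique())
    bmap = {b: i for i, b in enumerate(barcodes)}
    bc = frags["barcode"].map(bmap).to_numpy()
    cell_idx = bc[rows]

    counts = sp.coo_matrix(
        (np.ones(pos.size, dtype=np.int64), (cell_idx, tile_idx)),
        shape=(len(barcodes), int(tile_offsets[-1])),
    ).tocsr()
    depth = np.bincount(bc, weights=frags["count"].to_numpy(),
                        minlength=len(barcodes))
    return FeatureMatrix(counts, list(barcodes), labels, "tile", depth)


@dataclass
class PeakSet:
    """Fixed-width intervals centered on summits, non-overlapping."""

    table: pd.DataFrame  # chrom, start, end, peak_id, summit, score

    def __post_init__(self) -> None:
        widths = self.table["end"] - self.table["start"]
        if len(set(widths)) > 1:
            raise ValueError("peak widths not constant")
        t = self.table.sort_values(["chrom", "start"])
        same = t["chrom"].to_numpy()[1:] == t["chrom"].to_numpy()[:-1]
        if (same & (t["start"].to_numpy()[1:] < t["end"].to_numpy()[:-1])).any():
            raise ValueError("overlapping peaks")

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_truth(cls, truth_peaks: pd.DataFrame) -> "PeakSet":
        t = truth_peaks[["chrom", "start", "end", "peak_id"]].copy()
        t["summit"] = (t["start"] + t["end"]) // 2
        t["score"] = 0.0
        return cls(t.reset_index(drop=True))


def _greedy_summits(pos: np.ndarray, count: np.ndarray, width: int
                    ) -> np.ndarray:
    """Accept summits by descending count, skipping any within ``width``."""
    order = np.lexsort((pos, -count))
    accepted: list[int] = []
    acc_sorted: list[int] = []
    import bisect
    for i in order:
        p = int(pos[i])
        j = bisect.bisect_left(acc_sorted, p)
        if j > 0 and p - acc_sorted[j - 1] < width:
            continue
        if j < len(acc_sorted) and acc_sorted[j] - p < width:
            continue
        bisect.insort(acc_sorted, p)
        accepted.append(i)
    return np.array(accepted, dtype=int)


def call_peaks_pseudobulk(frag_groups: dict[str, pd.DataFrame], genome: Genome,
                          width: int = 500, pvalue: float = 1e-4) -> PeakSet:
    """Minimal pseudobulk peak caller over per-bp insertion pileups.

    Per group, candidate summits are local maxima whose insertion count has a
    Poisson upper-tail probability <= ``pvalue`` against the genome-wide mean
    rate; candidates from all groups are merged and resolved greedily by
    descending count with a ``width`` exclusion zone.
    """
    if not frag_groups:
        raise ValueError("no fragment groups")
    names, offsets = genome_offsets(genome)
    genome_bp = int(offsets[-1])
    cand_pos: list[np.ndarray] = []
    cand_count: list[np.ndarray] = []
    for label, frags in frag_groups.items():
        if len(frags) == 0:
            raise ValueError(f"group {label!r} has no fragments")
        pos, _ = insertion_positions(frags, genome, weighted=True)
        pileup = np.bincount(pos, minlength=genome_bp)
        lam = pos.size / genome_bp
        min_count = int(stats.poisson.isf(pvalue, lam)) + 1
        hot = np.flatnonzero(pileup >= max(min_count, 1))
        if hot.size == 0:
            continue
        c = pileup[hot]
        # local maximum within +/-1 bp (plateaus keep the leftmost position)
        left = np.where(hot - 1 >= 0, pileup[np.maximum(hot - 1, 0)], 0)
        right = np.where(hot + 1 < genome_bp,
                         pileup[np.minimum(hot + 1, genome_bp - 1)], 0)
        keep = (c > left) & (c >= right)
        cand_pos.append(hot[keep])
        cand_count.append(c[keep])
    if not cand_pos:
        return PeakSet(pd.DataFrame(
            columns=["chrom", "start", "end", "peak_id", "summit", "score"]))
    pos = np.concatenate(cand_pos)
    count = np.concatenate(cand_count).astype(float)
    # merge duplicate summit positions across groups, keeping the max count
    uniq, inv = np.unique(pos, return_inverse=True)
    best = np.zeros(uniq.size)
    np.maximum.at(best, inv, count)
    idx = _greedy_summits(uniq, best, width)
    summit = uniq[idx]
    score = best[idx]
    ci = np.searchsorted(offsets, summit, side="right") - 1
    local = summit - offsets[ci]
    start = np.clip(local - width // 2, 0, None)
    chrom_len = np.diff(offsets)[ci]
    start = np.minimum(start, chrom_len - width)
    table = pd.DataFrame({
        "chrom": [names[i] for i in ci],
        "start": start,
        "end": start + width,
        "summit": local,
        "score": score,
    }).sort_values(["chrom", "start"], ignore_index=True)
    # greedy exclusion guarantees summit spacing >= width within a chromosome,
    # but clipping at chromosome edges can still collide; drop overlaps
    same = table["chrom"].to_numpy()[1:] == table["chrom"].to_numpy()[:-1]
    bad = np.zeros(len(table), dtype=bool)
    bad[1:] = same & (table["start"].to_numpy()[1:] < table["end"].to_numpy()[:-1])
    table = table[~bad].reset_index(drop=True)
    table.insert(3, "peak_id", [f"called{i:05d}" for i in range(len(table))])
    return PeakSet(table)


def make_peak_matrix(frags: pd.DataFrame, peaks: PeakSet, genome: Genome,
                     ceiling: int = 4,
                     barcodes: list[str] | None = None) -> FeatureMatrix:
    """Cells x peaks insertion counts, capped at ``ceiling`` to limit outliers."""
    if barcodes is not None:
        frags = frags[frags["barcode"].isin(set(barcodes))].reset_index(drop=True)
    names, offsets = genome_offsets(genome)
    cmap = {c: i for i, c in enumerate(names)}
    t = peaks.table
    pci = t["chrom"].map(cmap).to_numpy(dtype=np.int64)
    pstart = t["start"].to_numpy() + offsets[pci]
    pend = t["end"].to_numpy() + offsets[pci]
    order = np.argsort(pstart)
    pstart_s, pend_s = pstart[order], pend[order]

    pos, rows = insertion_positions(frags, genome, weighted=True)
    pk = np.searchsorted(pstart_s, pos, side="right") - 1
    pkc = np.maximum(pk, 0)
    inside = (pk >= 0) & (pos < pend_s[pkc])

    if barcodes is None:
        barcodes = sorted(frags["barcode"].unique())
    bmap = {b: i for i, b in enumerate(barcodes)}
    bc = frags["barcode"].map(bmap).to_numpy()
    cell_idx = bc[rows[inside]]
    peak_idx = order[pkc[inside]]
    counts = sp.coo_matrix(
        (np.ones(inside.sum(), dtype=np.int64), (cell_idx, peak_idx)),
        shape=(len(barcodes), len(t)),
    ).tocsr()
    counts.data = np.minimum(counts.data, ceiling)
    depth = np.bincount(bc, weights=frags["count"].to_numpy(),
                        minlength=len(barcodes))
    labels = [
        GenomicInterval(c, s, e).label()
        for c, s, e in zip(t["chrom"], t["start"], t["end"])
    ]
    return FeatureMatrix(counts, list(barcodes), labels, "peak", depth)
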