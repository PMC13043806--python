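"""PWM scanning, hypergeometric motif enrichment, and Tn5 footprints.

The default motif mode is coordinate-based: the simulator plants motif
instances at known peak offsets, so no genome sequence is needed.  A
log-odds PWM scanner over explicit sequences is provided for real data.
Footprints aggregate Tn5 insertion counts around motif centers per cell
group and normalize by the outer flank, so a bound factor shows as a
central dip whose depth estimates the insertion-depletion factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from scipy import stats

from .differential import bh_fdr
from .features import Genome, genome_offsets, insertion_positions

log = logging.getLogger(__name__)

_BASES = "ACGT"


@dataclass
class PWM:
    name: str
    probs: np.ndarray  # 4 x L, rows A/C/G/T, columns sum to 1
    background: np.ndarray = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.background is None:
            self.background = np.full(4, 0.25)
        if self.probs.shape[0] != 4 or self.probs.shape[1] < 4:
            raise ValueError("PWM must be 4 x L with L >= 4")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.name}: columns must sum to 1")

    @property
    def length(self) -> int:
        return self.probs.shape[1]

    def log_odds(self, eps: float = 1e-9) -> np.ndarray:
        return np.log2((self.probs + eps) / self.background[:, None])

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=0).sum())


def read_jaspar(path: str | Path) -> list[PWM]:
    """Read JASPAR-format PWM text (counts or frequencies) via Bio.motifs."""
    out = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in _BASES], dtype=float)
            colsum = counts.sum(axis=0)
            colsum[colsum == 0] = 1.0
            out.append(PWM(m.name or m.matrix_id, counts / colsum))
    return out


def scan_pwm(sequences: dict[str, str], pwm: PWM,
             threshold_frac: float = 0.8) -> pd.DataFrame:
    """Log-odds scan of both strands; hits where score >= frac * max score.

    ``sequences`` maps peak id -> sequence.  Returns columns
    (motif, peak_id, offset, strand, score); offset is the hit start within
    the peak on the forward strand.
    """
    lo = pwm.log_odds()
    lo_rc = lo[::-1, ::-1]  # reverse complement: complement rows, reverse cols
    L = pwm.length
    threshold = threshold_frac * pwm.max_score()
    base_idx = {b: i for i, b in enumerate(_BASES)}
    rows = []
    for peak_id, seq in sequences.items():
        seq = seq.upper()
        if len(seq) < L:
            continue
        codes = np.array([base_idx.get(b, -1) for b in seq])
        for off in range(len(seq) - L + 1):
            window = codes[off:off + L]
            if (window < 0).any():
                continue
            fwd = float(lo[window, np.arange(L)].sum())
            rev = float(lo_rc[window, np.arange(L)].sum())
            if fwd >= threshold:
                rows.append((pwm.name, peak_id, off, "+", fwd))
            if rev >= threshold:
                rows.append((pwm.name, peak_id, off, "-", rev))
    return pd.DataFrame(rows, columns=["motif", "peak_id", "offset",
                                       "strand", "score"])


def planted_hits(truth_peaks: pd.DataFrame,
                 peak_ids: list[str] | None = None) -> pd.DataFrame:
    """Motif hits straight from the simulator's planted-motif table."""
    has = truth_peaks[truth_peaks["motif"] != ""]
    if peak_ids is not None:
        has = has[has["peak_id"].isin(set(peak_ids))]
    width = has["end"] - has["start"]
    return pd.DataFrame({
        "motif": has["motif"].to_numpy(),
        "peak_id": has["peak_id"].to_numpy(),
        "offset": (width // 2).to_numpy(),  # motif centered in the peak
        "strand": "+",
        "score": 0.0,
        "chrom": has["chrom"].to_numpy(),
        "center": ((has["start"] + has["end"]) // 2).to_numpy(),
    })


def motif_enrichment(hits: pd.DataFrame, marker_peaks: set[str],
                     all_peaks: set[str], fdr_threshold: float = 0.1,
                     log2fc_threshold: float = 0.1) -> pd.DataFrame:
    """Hypergeometric over-representation of motif-bearing peaks in markers.

    p = upper tail of drawing >= n_marker_with motif peaks when |marker|
    peaks are drawn from |all| containing n_all_with; log2fc compares the
    marker-set and universe hit rates.
    """
    if not marker_peaks:
        raise ValueError("empty marker peak set")
    if not marker_peaks <= all_peaks:
        raise ValueError("marker peaks must be a subset of all peaks")
    N, n_draw = len(all_peaks), len(marker_peaks)
    rows = []
    for motif, grp in hits.groupby("motif"):
        with_motif = set(grp["peak_id"]) & all_peaks
        K = len(with_motif)
        if K == 0:
            log.info("motif %s absent from the peak universe; skipped", motif)
            continue
        k = len(with_motif & marker_peaks)
        p = float(stats.hypergeom.sf(k - 1, N, K, n_draw))
        log2fc = float(np.log2((k / n_draw) / (K / N))) if k > 0 else -np.inf
        rows.append((motif, k, K, log2fc, p))
    out = pd.DataFrame(rows, columns=["motif", "n_marker_with", "n_all_with",
                                      "log2fc", "p"])
    if len(out):
        out["fdr"] = bh_fdr(out["p"].to_numpy())
        out["passes"] = (out["fdr"] <= fdr_threshold) \
            & (out["log2fc"] >= log2fc_threshold)
    return out


def footprint(frags: pd.DataFrame, hits: pd.DataFrame, genome: Genome,
              groups: pd.Series, flank: int = 250,
              norm_band: tuple[int, int] = (200, 250)) -> pd.DataFrame:
    """Aggregate insertion profile around motif centers, per cell group.

    ``hits`` needs chrom/center/strand columns (planted-hit table).  Counts
    at relative positions -flank..+flank are strand-oriented and summed over
    all hits; the normalized profile divides by the mean count over
    |pos| in [norm_band] (pseudocount 1 on the flank sum guards division).
    Returns a tidy frame (group, position, count, normalized).
    """
    if len(hits) == 0:
        raise ValueError("no motif hits")
    names, offsets = genome_offsets(genome)
    cmap = {c: i for i, c in enumerate(names)}
    hc = hits["chrom"].map(cmap).to_numpy(dtype=np.int64)
    centers = hits["center"].to_numpy() + offsets[hc]
    neg = (hits["strand"] == "-").to_numpy()
    order = np.argsort(centers)
    centers_s, neg_s = centers[order], neg[order]

    group_labels = groups.reindex(frags["barcode"]).to_numpy()
    width = 2 * flank + 1
    lo_b, hi_b = norm_band
    out = []
    for g in pd.unique(groups):
        sel = frags[group_labels == g]
        if len(sel) == 0:
            continue
        pos, _ = insertion_positions(sel, genome, weighted=True)
        j = np.searchsorted(centers_s, pos)
        prof = np.zeros(width)
        for cand in (j - 1, j):
            ok = (cand >= 0) & (cand < centers_s.size)
            rel = pos[ok] - centers_s[cand[ok]]
            rel = np.where(neg_s[cand[ok]], -rel, rel)
            keep = np.abs(rel) <= flank
            prof += np.bincount(rel[keep] + flank, minlength=width)
        positions = np.arange(-flank, flank + 1)
        band = (np.abs(positions) >= lo_b) & (np.abs(positions) <= hi_b)
        flank_mean = (prof[band].sum() + 1.0) / band.sum()
        out.append(pd.DataFrame({
            "group": g, "position": positions, "count": prof,
            "normalized": prof / flank_mean,
        }))
    if not out:
        raise ValueError("no fragments in any hit window")
    return pd.concat(out, ignore_index=True)
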