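"""Wilcoxon rank-sum marker detection with BH FDR control.

Each group is tested against all remaining cells, feature by feature, with a
tie-corrected rank-sum test; fold changes use pseudocounted means and the
Benjamini-Hochberg adjustment runs within each group across features.  The
gene-score flavor uses FDR <= 0.01 & log2FC >= 1.25, the peak flavor
FDR <= 0.1 & log2FC >= 0.5.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import MarkerConfig
from .io import FeatureMatrix


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum test: exact for small untied samples, otherwise a
    tie- and continuity-corrected normal approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        return float(x.size * y.size / 2.0), 1.0
    method = "exact" if (x.size + y.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone, order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _rank_and_ties(dense: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature mid-ranks and tie correction terms (group-independent)."""
    m = dense.shape[1]
    ranks = stats.rankdata(dense, axis=0)
    ties_term = np.empty(m)
    for j in range(m):
        _, counts = np.unique(dense[:, j], return_counts=True)
        ties_term[j] = np.sum(counts**3 - counts)
    return ranks, ties_term


def _ranksum_groups_vs_rest(ranks: np.ndarray, ties_term: np.ndarray,
                            in_group: np.ndarray) -> np.ndarray:
    """Vectorized two-sided tie-corrected normal rank-sum p per feature."""
    n = ranks.shape[0]
    n1 = int(in_group.sum())
    n2 = n - n1
    R1 = ranks[in_group].sum(axis=0)
    U = R1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - ties_term / (n * (n - 1)))
    sigma = np.sqrt(np.maximum(sigma2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.abs(U - mu) - 0.5) / sigma
    z = np.where(sigma == 0, 0.0, np.maximum(z, 0.0))
    return 2.0 * stats.norm.sf(z)


def marker_features(matrix: FeatureMatrix, groups: pd.Series | np.ndarray,
                    cfg: MarkerConfig) -> pd.DataFrame:
    """Group-vs-rest marker table for every group and feature.

    Columns: group, feature, mean_in, mean_out, log2fc, p_value, fdr, passes.
    log2fc = log2((mean_in + pc) / (mean_out + pc)); FDR within group.
    """
    labels = np.asarray(groups)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    dense = np.asarray(matrix.counts.todense(), dtype=float) \
        if sp.issparse(matrix.counts) else np.asarray(matrix.counts, float)
    features = np.array(matrix.features)
    ranks, ties_term = _rank_and_ties(dense)
    tables = []
    for g in uniq:
        in_group = labels == g
        if in_group.sum() == 0:
            raise ValueError(f"group {g!r} is empty")
        mean_in = dense[in_group].mean(axis=0)
        mean_out = dense[~in_group].mean(axis=0)
        log2fc = np.log2((mean_in + cfg.pseudocount)
                         / (mean_out + cfg.pseudocount))
        p = _ranksum_groups_vs_rest(ranks, ties_term, in_group)
        fdr = bh_fdr(p)
        passes = (fdr <= cfg.fdr) & (log2fc >= cfg.log2fc)
        tables.append(pd.DataFrame({
            "group": g, "feature": features, "mean_in": mean_in,
            "mean_out": mean_out, "log2fc": log2fc, "p_value": p,
            "fdr": fdr, "passes": passes,
        }))
    return pd.concat(tables, ignore_index=True)
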