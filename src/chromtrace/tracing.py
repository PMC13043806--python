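"""Tissue-of-origin tracing from metacell chromatin modules.

The readout of the whole pipeline: metacells are summarized by tissue
composition; chromatin modules associated with a tissue define peak-set
tissue signatures; held-out stromal cells are then assigned a tissue of
origin by Jaccard similarity between their binarized peak profile and each
signature.  A combinatorial gate (tissue-specific region AND cell-type
marker gene) reproduces the region+gene selection strategy for isolating
tissue-specific stromal cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .differential import marker_features
from .config import MarkerConfig
from .io import FeatureMatrix
from .metacells import MetacellAssignment
from .similarity import AccessibleSet, ModulePartition

log = logging.getLogger(__name__)


def tissue_composition(assignment: MetacellAssignment,
                       tissue_of: pd.Series) -> pd.DataFrame:
    """Fraction of each tissue within every metacell.

    Returns a metacell x tissue frame plus majority_tissue / purity columns;
    non-empty rows sum to 1, empty metacells are all-zero rows.
    """
    cells = assignment.cells.copy()
    cells["tissue"] = tissue_of.reindex(cells["barcode"]).to_numpy()
    if cells["tissue"].isna().any():
        raise ValueError("every assigned cell needs a tissue label")
    tissues = sorted(cells["tissue"].unique())
    n_meta = assignment.profiles.shape[0]
    F = pd.DataFrame(0.0, index=np.arange(1, n_meta + 1), columns=tissues)
    counts = cells.groupby(["metacell", "tissue"]).size().unstack(fill_value=0)
    sizes = counts.sum(axis=1)
    frac = counts.div(sizes, axis=0)
    F.loc[frac.index, frac.columns] = frac
    out = F.copy()
    nonzero = out.sum(axis=1) > 0
    out["majority_tissue"] = ""
    out.loc[nonzero, "majority_tissue"] = F.loc[nonzero].idxmax(axis=1)
    out["purity"] = F.max(axis=1)
    out["size"] = sizes.reindex(out.index).fillna(0).astype(int)
    return out


def celltype_metacell_correlation(assignment: MetacellAssignment,
                                  matrix: FeatureMatrix,
                                  type_of: pd.Series) -> pd.DataFrame:
    """Pearson r between cell-type and metacell aggregated peak profiles.

    Profiles are summed counts, depth-normalized to 10k and ln(1+x).
    Zero-variance profiles yield missing r, not 0.
    """
    def norm(v: np.ndarray) -> np.ndarray:
        tot = v.sum()
        return np.log1p(1e4 * v / tot) if tot > 0 else v

    bmap = {b: i for i, b in enumerate(matrix.barcodes)}
    rows = []
    meta_prof = {m: norm(assignment.profiles.loc[m].to_numpy())
                 for m in assignment.profiles.index}
    for ct in sorted(type_of.dropna().unique()):
        members = [bmap[b] for b in type_of.index[type_of == ct] if b in bmap]
        prof = norm(np.asarray(
            matrix.counts[np.array(members)].sum(axis=0)).ravel())
        for m, mp in meta_prof.items():
            if np.std(prof) == 0 or np.std(mp) == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(prof, mp)[0, 1])
            rows.append((ct, m, r))
    return pd.DataFrame(rows, columns=["cell_type", "metacell", "r"])


def build_tissue_signatures(modules: ModulePartition,
                            module_sets: dict[int, AccessibleSet],
                            peak_matrix: FeatureMatrix | None = None,
                            tissue_of: pd.Series | None = None,
                            fallback_top: int = 500,
                            marker_cfg: MarkerConfig | None = None
                            ) -> dict[str, frozenset[str]]:
    """Tissue -> peak-id signature from tissue-associated chromatin modules.

    A tissue's signature is the union of the accessible sets of its
    associated modules (each module's set is computed over the pooled cells
    of its member metacells, so the accessibility-fraction threshold beats
    stray background hits).  A tissue with no associated module falls back
    to its significantly differential peaks versus the rest, capped at
    ``fallback_top``; when nothing is significant the top-ranked peaks are
    used regardless, which yields a chance-level signature on null data.
    """
    assoc = modules.associations
    signatures: dict[str, frozenset[str]] = {}
    tissues = sorted(assoc["tissue"].unique())
    fallback_needed = []
    for tissue in tissues:
        mods = assoc.loc[(assoc["tissue"] == tissue) & assoc["associated"],
                         "module"]
        if len(mods) == 0:
            fallback_needed.append(tissue)
            continue
        peaks: set[str] = set()
        for m in mods:
            if m in module_sets:
                peaks |= set(module_sets[m].peaks)
        signatures[tissue] = frozenset(peaks)
    if fallback_needed:
        if peak_matrix is None or tissue_of is None:
            log.warning("no fallback data; tissues without modules skipped: %s",
                        fallback_needed)
        else:
            cfg = marker_cfg or MarkerConfig(fdr=0.1, log2fc=0.5)
            labels = tissue_of.reindex(peak_matrix.barcodes)
            table = marker_features(peak_matrix, labels.to_numpy(), cfg)
            for tissue in fallback_needed:
                sub = table[table["group"] == tissue]
                sig = sub[sub["passes"]]
                if len(sig) == 0:
                    sig = sub
                sig = sig.sort_values(["p_value", "feature"]).head(fallback_top)
                signatures[tissue] = frozenset(sig["feature"])
                log.info("tissue %s signature built by differential fallback",
                         tissue)
    if not any(signatures.values()):
        raise ValueError("no tissue has a non-empty signature")
    if len(signatures) >= 2:
        # tissue-specific means unique: peaks claimed by more than one
        # tissue (housekeeping and shared cell-type programs) carry no
        # origin information and are dropped from every signature
        counts: dict[str, int] = {}
        for peaks in signatures.values():
            for p in peaks:
                counts[p] = counts.get(p, 0) + 1
        signatures = {t: frozenset(p for p in peaks if counts[p] == 1)
                      for t, peaks in signatures.items()}
    return signatures


def predict_origin(matrix: FeatureMatrix,
                   signatures: dict[str, frozenset[str]]) -> pd.DataFrame:
    """Per-cell tissue prediction by Jaccard of binarized profile vs signature.

    Ties (including all-zero scores) give a missing prediction.  Cells with
    empty profiles are unclassified.
    """
    if len(signatures) < 2:
        raise ValueError("need at least two tissue signatures")
    feats = np.array(matrix.features)
    binary = (matrix.counts > 0).astype(np.float64).tocsr()
    tissues = sorted(signatures)
    sig_mask = np.stack([np.isin(feats, list(signatures[t])) for t in tissues])
    sig_sizes = sig_mask.sum(axis=1)
    inter = np.asarray((binary @ sig_mask.T.astype(float)))
    cell_sizes = np.asarray(binary.sum(axis=1)).ravel()
    union = cell_sizes[:, None] + sig_sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    best = np.argmax(score, axis=1)
    best_score = score[np.arange(len(best)), best]
    # a tie for the top score means no call
    sorted_scores = np.sort(score, axis=1)
    tied = (score.shape[1] >= 2) & (sorted_scores[:, -1] == sorted_scores[:, -2])
    predicted = np.array([tissues[b] for b in best], dtype=object)
    predicted[tied | (cell_sizes == 0)] = None
    return pd.DataFrame({
        "barcode": matrix.barcodes,
        "predicted_tissue": predicted,
        "score": best_score,
    })


def holdout_split(barcodes: list[str], fraction: float = 0.5, seed: int = 0
                  ) -> tuple[list[str], list[str]]:
    """Seeded train/test split; test cells never touch signature building."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(barcodes))
    n_train = int(round((1.0 - fraction) * len(barcodes)))
    train = [barcodes[i] for i in order[:n_train]]
    test = [barcodes[i] for i in order[n_train:]]
    return train, test


def prediction_accuracy(predictions: pd.DataFrame,
                        truth: pd.Series) -> float:
    """Fraction of classified cells predicted correctly."""
    merged = predictions.set_index("barcode")["predicted_tissue"]
    truth = truth.reindex(merged.index)
    called = merged.notna()
    if called.sum() == 0:
        return float("nan")
    return float((merged[called] == truth[called]).mean())


def combinatorial_gate(region_values: pd.Series, gene_values: pd.Series,
                       region_threshold: float, gene_threshold: float
                       ) -> pd.Index:
    """Cells passing BOTH strict thresholds (region AND marker gene)."""
    if not region_values.index.equals(gene_values.index):
        gene_values = gene_values.reindex(region_values.index)
    mask = (region_values > region_threshold) & (gene_values > gene_threshold)
    return region_values.index[mask.fillna(False)]


def marker_correlation(x: np.ndarray, y: np.ndarray,
                       method: str = "spearman") -> tuple[float, float]:
    """Correlation between two per-cell value vectors.

    Spearman is Pearson on mid-ranks; p is the t-approximation with n-2 df,
    replaced by an exact permutation p when n <= 8.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("need >= 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    if method == "pearson":
        rx, ry = x, y
    elif method == "spearman":
        rx, ry = stats.rankdata(x), stats.rankdata(y)
    else:
        raise ValueError(f"unknown method {method!r}")

    def corr(a: np.ndarray, b: np.ndarray) -> float:
        return float(np.corrcoef(a, b)[0, 1])

    rho = corr(rx, ry)
    if n <= 8:
        observed = abs(rho)
        count = 0
        total = 0
        for perm in permutations(range(n)):
            total += 1
            if abs(corr(rx, ry[list(perm)])) >= observed - 1e-12:
                count += 1
        return rho, count / total
    t = rho * np.sqrt((n - 2) / max(1.0 - rho**2, 1e-300))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(p)
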