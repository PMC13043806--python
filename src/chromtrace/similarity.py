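"""Accessible peak sets, Jaccard similarity, and chromatin modules.

Groups of cells (annotated cell types, or metacells) are reduced to the set
of peaks accessible in at least ``min_fraction`` of their cells; pairwise
Jaccard indices between those sets quantify regulatory similarity.  Blocks
of mutually similar metacells ("chromatin modules") are found by average-
linkage clustering of 1 - J and tested for tissue over-representation with a
hypergeometric test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .differential import bh_fdr
from .io import FeatureMatrix

log = logging.getLogger(__name__)


@dataclass
class AccessibleSet:
    label: str
    peaks: frozenset[str]
    min_fraction: float


def accessible_set(matrix: FeatureMatrix, cell_rows: np.ndarray, label: str,
                   min_fraction: float = 0.05) -> AccessibleSet:
    """Peaks nonzero in at least ``min_fraction`` of the group's cells."""
    if len(cell_rows) == 0:
        raise ValueError(f"empty group {label!r}")
    sub = matrix.counts[cell_rows]
    frac = np.asarray((sub > 0).sum(axis=0)).ravel() / len(cell_rows)
    if min_fraction == 0:
        keep = frac > 0
    else:
        keep = frac >= min_fraction
    feats = np.array(matrix.features)
    return AccessibleSet(label, frozenset(feats[keep]), min_fraction)


def jaccard_matrix(sets: list[AccessibleSet]) -> pd.DataFrame:
    """Symmetric matrix of Jaccard indices J = |A&B| / |A|B| between sets."""
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    universe = sorted(set().union(*(s.peaks for s in sets)))
    index = {p: i for i, p in enumerate(universe)}
    B = np.zeros((len(sets), len(universe)), dtype=bool)
    for i, s in enumerate(sets):
        for p in s.peaks:
            B[i, index[p]] = True
    inter = (B.astype(np.int64) @ B.T.astype(np.int64)).astype(float)
    sizes = B.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        J = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    if (union == 0).any():
        log.info("some set pairs are both empty; their Jaccard is 0")
    np.fill_diagonal(J, np.where(sizes > 0, 1.0, 0.0))
    labels = [s.label for s in sets]
    return pd.DataFrame(J, index=labels, columns=labels)


def intra_type_similarity(matrix: FeatureMatrix, cells: pd.DataFrame,
                          min_fraction: float = 0.05, min_cells: int = 20,
                          seed: int = 0) -> pd.Series:
    """Mean pairwise Jaccard among a cell type's per-tissue accessible sets.

    A type spread over several tissues contributes one accessible set per
    (type, tissue) with >= min_cells; a single-tissue type falls back to two
    seeded random halves (pseudo-replicates), so its value reflects sampling
    noise only.  Shared stromal types carrying tissue-level peaks score lower
    than organ-restricted types.
    """
    rng = np.random.default_rng(seed)
    bmap = {b: i for i, b in enumerate(matrix.barcodes)}
    cells = cells[cells["barcode"].isin(bmap)]
    out = {}
    for ct, grp in cells.groupby("cell_type"):
        if len(grp) < min_cells:
            raise ValueError(f"cell type {ct!r} has fewer than {min_cells} cells")
        sets = []
        for tissue, tgrp in grp.groupby("tissue"):
            if len(tgrp) < min_cells:
                continue
            rows = np.array([bmap[b] for b in tgrp["barcode"]])
            sets.append(accessible_set(matrix, rows, f"{ct}|{tissue}",
                                       min_fraction))
        if len(sets) < 2:
            rows = np.array([bmap[b] for b in grp["barcode"]])
            perm = rng.permutation(rows)
            halves = [perm[: len(perm) // 2], perm[len(perm) // 2:]]
            sets = [accessible_set(matrix, h, f"{ct}|half{i}", min_fraction)
                    for i, h in enumerate(halves)]
        J = jaccard_matrix(sets).to_numpy()
        iu = np.triu_indices(len(sets), k=1)
        out[ct] = float(J[iu].mean())
    return pd.Series(out, name="intra_type_jaccard")


@dataclass
class ModulePartition:
    assignment: pd.Series  # metacell label -> module id
    associations: pd.DataFrame  # module, tissue, overlap, p, fdr, associated


def detect_modules(similarity: pd.DataFrame, majority_tissue: pd.Series,
                   n_modules: int, fdr_threshold: float = 0.05
                   ) -> ModulePartition:
    """Average-linkage tree cut on 1 - J, plus tissue over-representation.

    For each (module, tissue) pair, the hypergeometric upper tail of drawing
    that many tissue-majority metacells into the module; BH-adjusted across
    all pairs, association declared at fdr < threshold.
    """
    n = similarity.shape[0]
    if n_modules > n:
        raise ValueError(f"n_modules ({n_modules}) exceeds metacells ({n})")
    D = 1.0 - similarity.to_numpy()
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    Z = average(squareform(D, checks=False))
    modules = fcluster(Z, t=n_modules, criterion="maxclust")
    assignment = pd.Series(modules, index=similarity.index, name="module")

    majority = majority_tissue.reindex(similarity.index)
    rows = []
    N = n
    for mod in np.unique(modules):
        members = assignment.index[assignment == mod]
        k_mod = len(members)
        for tissue in sorted(majority.dropna().unique()):
            K = int((majority == tissue).sum())
            overlap = int((majority.loc[members] == tissue).sum())
            p = float(stats.hypergeom.sf(overlap - 1, N, K, k_mod))
            rows.append((mod, tissue, overlap, k_mod, K, p))
    assoc = pd.DataFrame(rows, columns=["module", "tissue", "overlap",
                                        "module_size", "tissue_total", "p"])
    assoc["fdr"] = bh_fdr(assoc["p"].to_numpy())
    assoc["associated"] = assoc["fdr"] < fdr_threshold
    return ModulePartition(assignment, assoc)
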