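"""Ground-truth scATAC-seq fragment simulator.

Emulates the structure of a multi-tissue single-cell chromatin accessibility
atlas: several tissues share stromal cell types (endothelial, fibroblast,
macrophage analogues) while each tissue also carries an organ-restricted
parenchymal type.  Accessible regions come in three planted classes —

* housekeeping peaks: open in every cell of every tissue,
* tissue peaks: open in all cells of one tissue regardless of cell type
  (the chromatin tissue-of-origin signal the tracing analysis must recover),
* cell-type peaks: open in one cell type in every tissue.

Fragments have nucleosome-periodic lengths (nucleosome-free + mono-nucleosome
mixture), per-cell depths are lognormal, TSS enrichment arises because genes
are paired with planted peaks, doublet barcodes receive the union of two
cells' fragments, low-quality barcodes draw background only, and Tn5
insertion probability is depleted inside planted motif centers so aggregate
footprints carry a recoverable depletion factor.

Fragment endpoints are emitted as insertion positions directly (already
Tn5-shifted, 10x convention): insertions are ``start`` and ``end - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import read_bed, read_genes_tsv

_EDGE_MARGIN = 1000  # peaks keep this distance from chromosome ends
_MIN_GAP = 1000  # minimum gap between planted peaks
MOTIF_HALFWIDTH = 10  # depletion zone is motif center +/- this many bp


@dataclass
class SimConfig:
    seed: int = 0
    n_tissues: int = 9
    #: "{tissue}" in a type name expands per tissue, yielding organ-restricted types
    cell_types_per_tissue: tuple[str, ...] = (
        "endothelial", "fibroblast", "macrophage", "{tissue}_parenchyma",
    )
    n_cells_per_type: int = 60
    #: mini-genome scaled so the chance of a stray background hit in any one
    #: closed peak (~0.3% of cells at default depth) matches real libraries
    genome: tuple[tuple[str, int], ...] = (
        ("chr1", 30_000_000), ("chr2", 30_000_000), ("chr3", 30_000_000),
        ("chr4", 30_000_000), ("chr5", 30_000_000),
    )
    n_housekeeping_peaks: int = 200
    n_tissue_peaks_per_tissue: int = 40
    n_celltype_peaks_per_type: int = 20
    #: wide enough that the footprint window (+/-250 bp around a centered
    #: motif) sits in the flat interior of the insertion density, not on the
    #: peak-edge taper
    peak_width_bp: int = 1000
    signal_fraction: float = 0.6
    frags_per_cell_lognormal: tuple[float, float] = (np.log(2500.0), 0.35)
    #: (weights, (mean, sd) per component, truncation bounds)
    fraglen_weights: tuple[float, ...] = (0.7, 0.3)
    fraglen_components: tuple[tuple[float, float], ...] = ((75.0, 15.0), (220.0, 30.0))
    fraglen_bounds: tuple[float, float] = (20.0, 600.0)
    doublet_rate: float = 0.05
    lowq_cell_rate: float = 0.05
    lowq_frag_range: tuple[int, int] = (300, 800)
    footprint_depletion: float = 0.5
    #: motif name -> peak class carrying it ("housekeeping" | "tissue:<t>" | "celltype:<ct>")
    motif_peaks: dict[str, str] = field(default_factory=lambda: {
        "Klf1": "celltype:endothelial",
        "Runx1": "celltype:macrophage",
    })
    motif_width_bp: int = 12
    gene_body_bp: int = 2000

    def validate(self) -> None:
        if not 0.0 <= self.signal_fraction <= 1.0:
            raise ValueError("signal_fraction must be in [0, 1]")
        for name, rate in (("doublet_rate", self.doublet_rate),
                           ("lowq_cell_rate", self.lowq_cell_rate),
                           ("footprint_depletion", self.footprint_depletion)):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name, n in (("n_tissues", self.n_tissues),
                        ("n_cells_per_type", self.n_cells_per_type),
                        ("peak_width_bp", self.peak_width_bp)):
            if n <= 0:
                raise ValueError(f"{name} must be positive")
        for _, length in self.genome:
            if length <= 2 * _EDGE_MARGIN + self.peak_width_bp:
                raise ValueError("chromosome too short for peak placement")

    @property
    def tissues(self) -> list[str]:
        return [f"tissue{i + 1:02d}" for i in range(self.n_tissues)]

    def cell_types(self, tissue: str) -> list[str]:
        return [t.format(tissue=tissue) for t in self.cell_types_per_tissue]

    def all_cell_types(self) -> list[str]:
        seen: dict[str, None] = {}
        for tissue in self.tissues:
            for ct in self.cell_types(tissue):
                seen.setdefault(ct)
        return list(seen)

    def shared_cell_types(self) -> list[str]:
        """Types present in more than one tissue (the stromal analogues)."""
        counts: dict[str, int] = {}
        for tissue in self.tissues:
            for ct in set(self.cell_types(tissue)):
                counts[ct] = counts.get(ct, 0) + 1
        return [ct for ct, n in counts.items() if n > 1]


@dataclass
class TruthCatalog:
    """Planted peaks, paired genes, and the (tissue, cell type) accessibility map."""

    peaks: pd.DataFrame  # chrom, start, end, peak_id, klass, owner, motif
    genes: pd.DataFrame  # name, chrom, start, end, strand, tss, paired_peak

    def __post_init__(self) -> None:
        self._klass = self.peaks["klass"].to_numpy()
        self._owner = self.peaks["owner"].to_numpy()

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    def open_mask(self, tissue: str, cell_type: str) -> np.ndarray:
        """Boolean mask over peaks open in cells of (tissue, cell_type)."""
        return (
            (self._klass == "housekeeping")
            | ((self._klass == "tissue") & (self._owner == tissue))
            | ((self._klass == "celltype") & (self._owner == cell_type))
        )

    def tss_table(self) -> pd.DataFrame:
        return self.genes[["name", "chrom", "tss", "strand"]].copy()

    def motif_zones(self) -> pd.DataFrame:
        """Per motif-carrying peak: the depleted insertion zone (half-open)."""
        has = self.peaks[self.peaks["motif"] != ""].copy()
        center = ((has["start"] + has["end"]) // 2).to_numpy()
        has["zone_start"] = center - MOTIF_HALFWIDTH
        has["zone_end"] = center + MOTIF_HALFWIDTH + 1
        has["center"] = center
        return has


class PlacementError(RuntimeError):
    """Raised when non-overlapping peak placement fails within retry budget."""


def _place_peaks(rng: np.random.Generator, config: SimConfig,
                 n_peaks: int) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample non-overlapping peak placements genome-wide."""
    chrom_lengths = np.array([l for _, l in config.genome], dtype=np.int64)
    probs = chrom_lengths / chrom_lengths.sum()
    width = config.peak_width_bp
    chrom_idx = rng.choice(len(chrom_lengths), size=n_peaks, p=probs)
    start = (_EDGE_MARGIN + rng.random(n_peaks)
             * (chrom_lengths[chrom_idx] - width - 2 * _EDGE_MARGIN)
             ).astype(np.int64)
    for _ in range(200):
        order = np.lexsort((start, chrom_idx))
        ci, st = chrom_idx[order], start[order]
        ok = np.ones(n_peaks, dtype=bool)
        same = ci[1:] == ci[:-1]
        too_close = same & (st[1:] - st[:-1] < width + _MIN_GAP)
        ok[1:][too_close] = False
        if ok.all():
            return ci, st
        # resample only the colliding placements, keep the rest
        bad = order[~ok]
        chrom_idx_new = rng.choice(len(chrom_lengths), size=bad.size, p=probs)
        chrom_idx[bad] = chrom_idx_new
        start[bad] = (_EDGE_MARGIN + rng.random(bad.size)
                      * (chrom_lengths[chrom_idx_new] - width
                         - 2 * _EDGE_MARGIN)).astype(np.int64)
    raise PlacementError(
        f"could not place {n_peaks} non-overlapping peaks on the configured "
        f"genome after 200 attempts; enlarge the genome or reduce peak counts"
    )


def build_truth(config: SimConfig) -> TruthCatalog:
    """Plant peaks, assign classes/owners/motifs, and pair genes.

    Deterministic given ``config.seed``.  Housekeeping and cell-type peaks are
    paired with a gene whose TSS sits at the peak center, so gene activity
    scores and TSS enrichment both reflect the planted structure.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    chrom_names = [c for c, _ in config.genome]

    classes: list[tuple[str, str]] = []
    classes += [("housekeeping", "")] * config.n_housekeeping_peaks
    for tissue in config.tissues:
        classes += [("tissue", tissue)] * config.n_tissue_peaks_per_tissue
    for ct in config.all_cell_types():
        classes += [("celltype", ct)] * config.n_celltype_peaks_per_type
    n_peaks = len(classes)

    chrom_idx, start = _place_peaks(rng, config, n_peaks)
    klass = np.array([k for k, _ in classes])
    owner = np.array([o for _, o in classes])
    # shuffle class assignment over placements so classes are not position-ordered
    perm = rng.permutation(n_peaks)
    klass, owner = klass[perm], owner[perm]

    motif = np.full(n_peaks, "", dtype=object)
    for motif_name, spec in config.motif_peaks.items():
        if ":" in spec:
            k, o = spec.split(":", 1)
            mask = (klass == k) & (owner == o)
        else:
            mask = klass == spec
        motif[mask] = motif_name

    peaks = pd.DataFrame({
        "chrom": [chrom_names[i] for i in chrom_idx],
        "start": start,
        "end": start + config.peak_width_bp,
        "peak_id": [f"peak{i:05d}" for i in range(n_peaks)],
        "klass": klass,
        "owner": owner,
        "motif": motif,
    })

    gene_rows = []
    counters: dict[str, int] = {}
    half_body = config.gene_body_bp
    for row in peaks.itertuples():
        if row.klass == "tissue":
            continue
        tss = (row.start + row.end) // 2
        strand = "+" if (counters.get("_n", 0) % 2 == 0) else "-"
        counters["_n"] = counters.get("_n", 0) + 1
        if row.klass == "housekeeping":
            key = "hk"
            name = f"Hk{counters.get(key, 0) + 1:04d}"
        else:
            key = row.owner
            name = f"{row.owner.capitalize()}Mk{counters.get(key, 0) + 1:03d}"
        counters[key] = counters.get(key, 0) + 1
        if strand == "+":
            body = (tss, tss + half_body)
        else:
            body = (tss - half_body + 1, tss + 1)
        gene_rows.append((name, row.chrom, body[0], body[1], strand, tss, row.peak_id))
    genes = pd.DataFrame(
        gene_rows,
        columns=["name", "chrom", "start", "end", "strand", "tss", "paired_peak"],
    )
    return TruthCatalog(peaks=peaks, genes=genes)


def _build_cells(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for tissue in config.tissues:
        for ct in config.cell_types(tissue):
            for _ in range(config.n_cells_per_type):
                rows.append((tissue, ct, False, "", "", False))
    n_singlet = len(rows)
    n_lowq = int(round(config.lowq_cell_rate * n_singlet))
    combos = [(t, ct) for t in config.tissues for ct in config.cell_types(t)]
    for i in range(n_lowq):
        t, ct = combos[i % len(combos)]
        rows.append((t, ct, False, "", "", True))
    cells = pd.DataFrame(
        rows, columns=["tissue", "cell_type", "is_doublet",
                       "partner_a", "partner_b", "is_lowq"])
    cells.insert(0, "barcode", [f"BC{i:06d}" for i in range(len(cells))])

    mu, sigma = config.frags_per_cell_lognormal
    n_frags = np.rint(rng.lognormal(mu, sigma, size=len(cells))).astype(np.int64)
    lo, hi = config.lowq_frag_range
    lowq_mask = cells["is_lowq"].to_numpy()
    n_frags[lowq_mask] = rng.integers(lo, hi + 1, size=lowq_mask.sum())
    cells["target_fragments"] = np.maximum(n_frags, 1)

    n_doublets = int(round(config.doublet_rate * n_singlet))
    singlet_bc = cells["barcode"].to_numpy()[:n_singlet]
    drows = []
    for i in range(n_doublets):
        a, b = rng.choice(n_singlet, size=2, replace=False)
        drows.append((f"DB{i:06d}", cells.at[a, "tissue"], cells.at[a, "cell_type"],
                      True, singlet_bc[a], singlet_bc[b], False, 0))
    if drows:
        cells = pd.concat(
            [cells, pd.DataFrame(drows, columns=list(cells.columns))],
            ignore_index=True)
    return cells


def _sample_fraglen(rng: np.random.Generator, config: SimConfig, n: int) -> np.ndarray:
    weights = np.asarray(config.fraglen_weights, dtype=float)
    weights = weights / weights.sum()
    comp = rng.choice(len(weights), size=n, p=weights)
    means = np.array([m for m, _ in config.fraglen_components])
    sds = np.array([s for _, s in config.fraglen_components])
    length = rng.normal(means[comp], sds[comp])
    lo, hi = config.fraglen_bounds
    bad = (length < lo) | (length > hi)
    while bad.any():  # truncation by resampling
        idx = np.flatnonzero(bad)
        comp_i = rng.choice(len(weights), size=idx.size, p=weights)
        length[idx] = rng.normal(means[comp_i], sds[comp_i])
        bad = (length < lo) | (length > hi)
    return np.maximum(np.rint(length).astype(np.int64), 1)


def _zone_membership(pos: np.ndarray, zone_start: np.ndarray,
                     zone_end: np.ndarray) -> np.ndarray:
    """Membership of global positions in sorted disjoint half-open zones."""
    if zone_start.size == 0:
        return np.zeros(pos.shape, dtype=bool)
    idx = np.searchsorted(zone_start, pos, side="right") - 1
    idx_clip = np.maximum(idx, 0)
    return (idx >= 0) & (pos < zone_end[idx_clip])


def simulate_fragments(
    catalog: TruthCatalog, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the fragment table and the per-barcode truth table.

    Per cell, N ~ lognormal fragments; each is a peak fragment with
    probability ``signal_fraction`` (uniform among the peaks open for the
    cell's tissue/type, midpoint uniform inside the peak) and a uniform
    background fragment otherwise.  Insertions falling in a planted motif's
    central +/-10 bp are thinned by ``footprint_depletion``.  Low-quality
    barcodes draw background only; doublet barcodes receive the union of two
    singlets' fragments.  Output is sorted by (chrom, start).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    cells = _build_cells(config, rng)

    chrom_names = [c for c, _ in config.genome]
    chrom_lengths = np.array([l for _, l in config.genome], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(chrom_lengths)])
    genome_bp = int(offsets[-1])
    chrom_of = {c: i for i, c in enumerate(chrom_names)}

    peak_chrom = catalog.peaks["chrom"].map(chrom_of).to_numpy()
    peak_gstart = catalog.peaks["start"].to_numpy() + offsets[peak_chrom]
    width = config.peak_width_bp

    zones = catalog.motif_zones()
    z_chrom = zones["chrom"].map(chrom_of).to_numpy()
    z_start_all = (zones["zone_start"].to_numpy()
                   + offsets[z_chrom]).astype(np.int64)
    z_end_all = (zones["zone_end"].to_numpy()
                 + offsets[z_chrom]).astype(np.int64)
    z_peak_row = zones.index.to_numpy()  # catalog row of each zone's peak
    keep_prob = 1.0 - config.footprint_depletion

    real = cells[~cells["is_doublet"]]
    frag_cell: list[np.ndarray] = []
    frag_start: list[np.ndarray] = []
    frag_len: list[np.ndarray] = []

    for (tissue, ct, lowq), grp in real.groupby(
            ["tissue", "cell_type", "is_lowq"], sort=True):
        open_mask = catalog.open_mask(tissue, ct)
        open_idx = np.flatnonzero(open_mask)
        # a TF footprint exists only where the site is in open chromatin,
        # so insertion thinning applies per group to its open motif peaks
        z_sel = open_mask[z_peak_row]
        z_start = np.sort(z_start_all[z_sel])
        z_end = np.sort(z_end_all[z_sel])
        counts = grp["target_fragments"].to_numpy()
        cell_rows = np.repeat(grp.index.to_numpy(), counts)
        n = cell_rows.size
        lengths = _sample_fraglen(rng, config, n)
        sig_frac = 0.0 if (lowq or open_idx.size == 0) else config.signal_fraction
        is_signal = rng.random(n) < sig_frac

        gstart = np.empty(n, dtype=np.int64)
        n_bg = int((~is_signal).sum())
        if n_bg:
            # background: uniform midpoint genome-wide, kept inside the chromosome
            mid = (rng.random(n_bg) * genome_bp).astype(np.int64)
            ci = np.searchsorted(offsets, mid, side="right") - 1
            s = mid - lengths[~is_signal] // 2
            s = np.clip(s, offsets[ci], offsets[ci + 1] - lengths[~is_signal])
            gstart[~is_signal] = s
        n_sig = int(is_signal.sum())
        if n_sig:
            pk = open_idx[rng.integers(0, open_idx.size, size=n_sig)]
            mid = peak_gstart[pk] + rng.integers(0, width, size=n_sig)
            gstart[is_signal] = mid - lengths[is_signal] // 2

        if keep_prob < 1.0 and z_start.size:
            in1 = _zone_membership(gstart, z_start, z_end)
            pos2 = gstart + lengths - 1
            in2 = _zone_membership(pos2, z_start, z_end)
            keep = ((~in1) | (rng.random(n) < keep_prob)) & \
                   ((~in2) | (rng.random(n) < keep_prob))
        else:
            keep = np.ones(n, dtype=bool)
        frag_cell.append(cell_rows[keep])
        frag_start.append(gstart[keep])
        frag_len.append(lengths[keep])

    cell_idx = np.concatenate(frag_cell)
    gstart = np.concatenate(frag_start)
    lengths = np.concatenate(frag_len)

    # doublets: union of both partners' fragments under the doublet barcode
    doublets = cells[cells["is_doublet"]]
    if len(doublets):
        order = np.argsort(cell_idx, kind="stable")
        sorted_cells = cell_idx[order]
        bc_to_row = {b: i for i, b in enumerate(cells["barcode"])}
        extra_rows, extra_src = [], []
        for drow in doublets.itertuples():
            for partner in (drow.partner_a, drow.partner_b):
                r = bc_to_row[partner]
                lo = np.searchsorted(sorted_cells, r, side="left")
                hi = np.searchsorted(sorted_cells, r, side="right")
                src = order[lo:hi]
                extra_src.append(src)
                extra_rows.append(np.full(src.size, drow.Index, dtype=np.int64))
        if extra_src:
            src = np.concatenate(extra_src)
            cell_idx = np.concatenate([cell_idx, np.concatenate(extra_rows)])
            gstart = np.concatenate([gstart, gstart[src]])
            lengths = np.concatenate([lengths, lengths[src]])

    ci = np.searchsorted(offsets, gstart, side="right") - 1
    local_start = gstart - offsets[ci]
    barcodes = cells["barcode"].to_numpy()
    frags = pd.DataFrame({
        "chrom": pd.Categorical.from_codes(ci, categories=chrom_names),
        "start": local_start,
        "end": local_start + lengths,
        "barcode": barcodes[cell_idx],
        "count": np.ones(cell_idx.size, dtype=np.int64),
    })
    frags = frags.sort_values(["chrom", "start"], kind="stable",
                              ignore_index=True)
    frags["chrom"] = frags["chrom"].astype(str)
    return frags, cells


def expected_marker_peaks(catalog: TruthCatalog, config: SimConfig,
                          log2fc_threshold: float,
                          pseudocount: float = 0.1) -> dict[str, set[str]]:
    """Truth-derived expected marker-peak sets per cell type.

    Independent closed-form oracle for the group-vs-rest differential test:
    under the generative model an open peak saturates the capped peak-matrix
    count (~4) in nearly every open cell, so the predicted fold change for a
    peak is log2((4*f_in + pc) / (4*f_out + pc)) where f_in/f_out are open-cell
    fractions from the planted accessibility map.  A peak is an expected marker
    of a type when this exceeds the threshold.  Note an organ-restricted type
    inherits its organ's tissue peaks as genuine markers.
    """
    combos = [(t, ct) for t in config.tissues for ct in config.cell_types(t)]
    n_per = config.n_cells_per_type
    open_by_combo = {c: catalog.open_mask(*c) for c in combos}
    all_types = config.all_cell_types()
    total = n_per * len(combos)
    result: dict[str, set[str]] = {}
    peak_ids = catalog.peaks["peak_id"].to_numpy()
    for ct in all_types:
        in_open = np.zeros(catalog.n_peaks)
        out_open = np.zeros(catalog.n_peaks)
        n_in = 0
        for combo, mask in open_by_combo.items():
            if combo[1] == ct:
                in_open += n_per * mask
                n_in += n_per
            else:
                out_open += n_per * mask
        f_in = in_open / max(n_in, 1)
        f_out = out_open / max(total - n_in, 1)
        lfc = np.log2((4.0 * f_in + pseudocount) / (4.0 * f_out + pseudocount))
        result[ct] = set(peak_ids[lfc >= log2fc_threshold])
    return result


def write_truth(catalog: TruthCatalog, cells: pd.DataFrame,
                out_dir: str | Path) -> None:
    """Emit peaks BED (+class/owner/motif columns), genes TSV, cell-truth TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalog.peaks.to_csv(out / "truth_peaks.bed", sep="\t",
                         header=False, index=False)
    catalog.genes.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    cells.to_csv(out / "truth_cells.tsv", sep="\t", index=False)


def read_truth(in_dir: str | Path) -> tuple[TruthCatalog, pd.DataFrame]:
    in_dir = Path(in_dir)
    peaks = read_bed(in_dir / "truth_peaks.bed")
    peaks.columns = ["chrom", "start", "end", "peak_id", "klass", "owner", "motif"]
    peaks["owner"] = peaks["owner"].fillna("").astype(str).replace("nan", "")
    peaks["motif"] = peaks["motif"].fillna("").astype(str).replace("nan", "")
    genes = read_genes_tsv(in_dir / "truth_genes.tsv")
    cells = pd.read_csv(in_dir / "truth_cells.tsv", sep="\t",
                        keep_default_na=False,
                        dtype={"partner_a": str, "partner_b": str})
    return TruthCatalog(peaks=peaks, genes=genes), cells
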