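"""Generator contracts: determinism, planted structure, generative rates."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromtrace.simulate import (MOTIF_HALFWIDTH, PlacementError, SimConfig,
                                 build_truth, read_truth, simulate_fragments,
                                 write_truth)
from conftest import tiny_sim_config


class TestBuildTruth:
    def test_same_seed_gives_identical_catalogs(self):
        cfg = tiny_sim_config()
        a, b = build_truth(cfg), build_truth(tiny_sim_config())
        assert a.peaks.to_csv() == b.peaks.to_csv()
        assert a.genes.to_csv() == b.genes.to_csv()

    def test_peak_class_census_follows_config(self):
        cfg = tiny_sim_config(n_tissues=9, n_tissue_peaks_per_tissue=10,
                              n_cells_per_type=2)
        cat = build_truth(cfg)
        census = cat.peaks["klass"].value_counts()
        assert census["tissue"] == 90  # 9 tissues x 10 peaks
        assert census["housekeeping"] == cfg.n_housekeeping_peaks

    def test_zero_tissue_peaks_leaves_class_empty(self):
        cat = build_truth(tiny_sim_config(n_tissue_peaks_per_tissue=0))
        assert set(cat.peaks["klass"]) == {"housekeeping", "celltype"}

    def test_peaks_non_overlapping(self, tiny_sim):
        p = tiny_sim["catalog"].peaks.sort_values(["chrom", "start"])
        same = p["chrom"].to_numpy()[1:] == p["chrom"].to_numpy()[:-1]
        assert (p["start"].to_numpy()[1:][same]
                >= p["end"].to_numpy()[:-1][same]).all()

    def test_every_celltype_peak_has_nearby_gene(self, tiny_sim):
        cat = tiny_sim["catalog"]
        ct_peaks = cat.peaks[cat.peaks["klass"] == "celltype"]
        paired = cat.genes.set_index("paired_peak")
        for row in ct_peaks.itertuples():
            gene = paired.loc[row.peak_id]
            assert abs(gene["tss"] - (row.start + row.end) // 2) <= 25_000

    def test_accessibility_map_partitions_classes(self, tiny_sim):
        cat, cfg = tiny_sim["catalog"], tiny_sim["config"]
        mask = cat.open_mask("tissue01", "endothelial")
        k = cat.peaks["klass"].to_numpy()
        o = cat.peaks["owner"].to_numpy()
        assert mask[k == "housekeeping"].all()
        assert mask[(k == "tissue") & (o == "tissue01")].all()
        assert not mask[(k == "tissue") & (o == "tissue02")].any()
        assert not mask[(k == "celltype") & (o == "macrophage")].any()

    def test_capacity_error_when_genome_too_small(self):
        cfg = tiny_sim_config(genome=(("chr1", 200_000),),
                              n_housekeeping_peaks=500)
        with pytest.raises(PlacementError):
            build_truth(cfg)


class TestSimulateFragments:
    def test_background_only_limit_matches_genome_fraction(self):
        cfg = tiny_sim_config(signal_fraction=0.0, n_cells_per_type=5,
                              doublet_rate=0, lowq_cell_rate=0)
        cat = build_truth(cfg)
        frags, _ = simulate_fragments(cat, cfg)
        peaks = cat.peaks.sort_values(["chrom", "start"])
        frac = _overlap_fraction(frags, peaks)
        genome_bp = sum(l for _, l in cfg.genome)
        peak_bp = (peaks["end"] - peaks["start"]).sum()
        # fragment overlaps peak slightly more often than midpoint-in-peak
        expected = peak_bp / genome_bp
        assert abs(frac - expected) < 0.01

    def test_in_peak_fraction_recovers_signal_fraction(self, tiny_sim):
        cfg, cat = tiny_sim["config"], tiny_sim["catalog"]
        cells = tiny_sim["cells"]
        singlets = cells[~cells["is_doublet"] & ~cells["is_lowq"]]["barcode"]
        frags = tiny_sim["frags"]
        frags = frags[frags["barcode"].isin(set(singlets))]
        frac = _overlap_fraction(frags, cat.peaks.sort_values(["chrom", "start"]))
        assert abs(frac - cfg.signal_fraction) < 0.03

    def test_total_depletion_empties_motif_centers(self):
        """Carrier cells leave zero insertions in fully depleted motif zones."""
        cfg = tiny_sim_config(footprint_depletion=1.0, n_cells_per_type=5)
        cat = build_truth(cfg)
        frags, cells = simulate_fragments(cat, cfg)
        carriers = set(cells[cells["cell_type"] == "endothelial"]["barcode"])
        frags = frags[frags["barcode"].isin(carriers)]
        zones = cat.motif_zones()
        ins = pd.concat([
            frags[["chrom", "start"]].rename(columns={"start": "pos"}),
            pd.DataFrame({"chrom": frags["chrom"],
                          "pos": frags["end"] - 1})])
        for z in zones.itertuples():
            hit = ins[(ins["chrom"] == z.chrom) & (ins["pos"] >= z.zone_start)
                      & (ins["pos"] < z.zone_end)]
            assert len(hit) == 0

    def test_fragment_count_distribution_is_lognormal(self):
        cfg = tiny_sim_config(n_tissues=3, n_cells_per_type=112,  # ~1000 cells
                              doublet_rate=0, lowq_cell_rate=0,
                              motif_peaks={})
        cat = build_truth(cfg)
        frags, cells = simulate_fragments(cat, cfg)
        counts = frags.groupby("barcode").size()
        mu, sigma = cfg.frags_per_cell_lognormal
        stat = stats.kstest(counts.to_numpy(),
                            lambda x: stats.lognorm.cdf(x, s=sigma,
                                                        scale=np.exp(mu)))
        assert stat.statistic < 1.63 / np.sqrt(len(counts))  # alpha = 0.01

    def test_doublets_union_partner_fragments(self, tiny_sim):
        frags, cells = tiny_sim["frags"], tiny_sim["cells"]
        counts = frags.groupby("barcode").size()
        doublets = cells[cells["is_doublet"]]
        assert (doublets["partner_a"] != doublets["partner_b"]).all()
        for d in doublets.head(5).itertuples():
            assert counts[d.barcode] == counts[d.partner_a] + counts[d.partner_b]

    def test_lowq_cells_are_shallow_background(self, tiny_sim):
        frags, cells = tiny_sim["frags"], tiny_sim["cells"]
        cfg = tiny_sim["config"]
        lowq = set(cells[cells["is_lowq"]]["barcode"])
        counts = frags[frags["barcode"].isin(lowq)].groupby("barcode").size()
        lo, hi = cfg.lowq_frag_range
        assert counts.between(lo * 0.9, hi).all()

    def test_tissue_peak_sharing_across_cell_types(self, tiny_sim):
        """Any tissue peak is covered in >=95% of that tissue's good cells."""
        cfg, cat = tiny_sim["config"], tiny_sim["catalog"]
        frags, cells = tiny_sim["frags"], tiny_sim["cells"]
        good = cells[~cells["is_lowq"] & ~cells["is_doublet"]
                     & (cells["tissue"] == "tissue01")]
        tpeaks = cat.peaks[(cat.peaks["klass"] == "tissue")
                           & (cat.peaks["owner"] == "tissue01")].head(4)
        sub = frags[frags["barcode"].isin(set(good["barcode"]))]
        for pk in tpeaks.itertuples():
            cov = sub[(sub["chrom"] == pk.chrom) & (sub["end"] > pk.start)
                      & (sub["start"] < pk.end)]["barcode"].nunique()
            assert cov >= 0.95 * len(good)

    def test_output_sorted_by_chrom_start(self, tiny_sim):
        frags = tiny_sim["frags"]
        key = pd.MultiIndex.from_frame(frags[["chrom", "start"]])
        assert key.is_monotonic_increasing


class TestWriteTruth:
    def test_round_trip(self, tiny_sim, tmp_path):
        cat, cells = tiny_sim["catalog"], tiny_sim["cells"]
        write_truth(cat, cells, tmp_path)
        cat2, cells2 = read_truth(tmp_path)
        pd.testing.assert_frame_equal(cat.peaks.reset_index(drop=True),
                                      cat2.peaks, check_dtype=False)
        pd.testing.assert_frame_equal(cat.genes, cat2.genes, check_dtype=False)
        pd.testing.assert_frame_equal(cells, cells2, check_dtype=False)

    def test_empty_cell_table_is_header_only(self, tiny_sim, tmp_path):
        write_truth(tiny_sim["catalog"], tiny_sim["cells"].iloc[0:0], tmp_path)
        text = (tmp_path / "truth_cells.tsv").read_text().strip().splitlines()
        assert len(text) == 1 and text[0].startswith("barcode")

    def test_bed_is_zero_based_half_open(self, tiny_sim, tmp_path):
        write_truth(tiny_sim["catalog"], tiny_sim["cells"], tmp_path)
        line = (tmp_path / "truth_peaks.bed").read_text().splitlines()[0]
        chrom, start, end = line.split("\t")[:3]
        row = tiny_sim["catalog"].peaks.iloc[0]
        assert int(start) == row["start"] and int(end) == row["end"]
        assert int(end) - int(start) == tiny_sim["config"].peak_width_bp


def _overlap_fraction(frags: pd.DataFrame, peaks: pd.DataFrame) -> float:
    """Fraction of fragments overlapping any peak (interval intersection)."""
    total = 0
    hits = 0
    for chrom, sub in frags.groupby("chrom", observed=True):
        p = peaks[peaks["chrom"] == chrom]
        starts = p["start"].to_numpy()
        ends = p["end"].to_numpy()
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        idx = np.searchsorted(starts, e, side="left") - 1
        idxc = np.maximum(idx, 0)
        overlap = (idx >= 0) & (s < ends[idxc])
        total += len(sub)
        hits += int(overlap.sum())
    return hits / total
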