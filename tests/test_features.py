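"""Tile/peak counting conventions and the pseudobulk peak caller."""

import numpy as np
import pandas as pd
import pytest

from chromtrace.features import (PeakSet, call_peaks_pseudobulk,
                                 make_peak_matrix, make_tile_matrix)

GENOME = [("chr1", 20_000), ("chr2", 12_000)]


def _frags(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "barcode",
                                       "count"])


def _peaks(rows, width=None):
    t = pd.DataFrame(rows, columns=["chrom", "start", "end", "peak_id"])
    t["summit"] = (t["start"] + t["end"]) // 2
    t["score"] = 0.0
    return PeakSet(t)


class TestTileMatrix:
    def test_boundary_fragment_splits_between_tiles(self):
        m = make_tile_matrix(_frags([("chr1", 4999, 5001, "b", 1)]), GENOME)
        col = {f: i for i, f in enumerate(m.features)}
        assert m.counts[0, col["chr1:0-5000"]] == 1       # insertion at 4999
        assert m.counts[0, col["chr1:5000-10000"]] == 1   # insertion at 5000

    def test_both_insertions_in_one_tile(self):
        m = make_tile_matrix(_frags([("chr1", 10, 20, "b", 1)]), GENOME)
        assert m.counts[0, 0] == 2

    def test_insertion_conservation_weighted_by_count(self):
        rng = np.random.default_rng(0)
        rows = [("chr1", int(s), int(s) + 50, f"b{i % 4}", int(c))
                for i, (s, c) in enumerate(zip(rng.integers(0, 19_000, 100),
                                               rng.integers(1, 4, 100)))]
        frags = _frags(rows)
        m = make_tile_matrix(frags, GENOME)
        assert m.counts.sum() == 2 * frags["count"].sum()

    def test_partial_last_tile_and_order_invariance(self):
        frags = _frags([("chr2", 11_000, 11_500, "b", 1),
                        ("chr1", 100, 400, "b", 1)])
        m1 = make_tile_matrix(frags, GENOME)
        m2 = make_tile_matrix(frags.iloc[::-1].reset_index(drop=True), GENOME)
        assert m1.features[-1] == "chr2:10000-12000"
        assert (m1.counts != m2.counts).nnz == 0

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(KeyError, match="chrMT"):
            make_tile_matrix(_frags([("chrMT", 0, 10, "b", 1)]), GENOME)


class TestPeakMatrix:
    @pytest.mark.parametrize("n_insertions,stored", [(7, 4), (3, 3), (4, 4)])
    def test_ceiling_caps_counts(self, n_insertions, stored):
        # n single-insertion-pair fragments = 2n insertions; use half in peak
        rows = [("chr1", 1000 + 2 * i, 6000 + 2 * i, "b", 1)
                for i in range(n_insertions)]  # starts in peak, ends outside
        peaks = _peaks([("chr1", 900, 1900, "p1")])
        m = make_peak_matrix(_frags(rows), peaks, GENOME, ceiling=4)
        assert m.counts[0, 0] == stored

    def test_overlapping_peaks_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            _peaks([("chr1", 0, 1000, "a"), ("chr1", 500, 1500, "b")])

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        rows = [("chr1", int(s), int(s) + 60, f"b{i % 3}", 1)
                for i, s in enumerate(rng.integers(0, 19_000, 300))]
        peaks = _peaks([("chr1", 2000, 3000, "p1"), ("chr1", 8000, 9000, "p2")])
        m1 = make_peak_matrix(_frags(rows), peaks, GENOME)
        m2 = make_peak_matrix(_frags(rows).sample(frac=1, random_state=2),
                              peaks, GENOME)
        assert (m1.counts != m2.counts).nnz == 0


class TestPeakCaller:
    def test_single_hot_site_is_called(self):
        rng = np.random.default_rng(0)
        bg = [("chr1", int(s), int(s) + 100, "b", 1)
              for s in rng.integers(0, 19_000, 50)]
        hot = [("chr1", 9_950, 10_050, "b", 1)] * 25  # 50 insertions at 2 sites
        peaks = call_peaks_pseudobulk({"g": _frags(bg + hot)}, GENOME,
                                      width=500)
        assert len(peaks) >= 1
        assert (np.abs(peaks.table["summit"] - 10_000) <= 60).any()

    def test_flat_poisson_background_stays_within_false_call_budget(self):
        # the per-position tail cutoff implies at most ~1e-4 * genome_bp
        # false candidates in expectation; a flat field should yield at most
        # a handful of calls and typically none
        rng = np.random.default_rng(3)
        rows = []
        for chrom, length in GENOME:
            rows += [(chrom, int(s), int(s) + 80, "b", 1)
                     for s in rng.integers(0, length - 100, 1000)]
        peaks = call_peaks_pseudobulk({"g": _frags(rows)}, GENOME, width=500)
        assert len(peaks) <= 3

    def test_close_summits_resolved_greedily(self):
        a = [("chr1", 5_000, 5_001, "b", 1)] * 30   # 60 insertions at 5000/5000
        b = [("chr1", 5_100, 5_101, "b", 1)] * 20
        peaks = call_peaks_pseudobulk({"g": _frags(a + b)}, GENOME, width=500)
        assert len(peaks) == 1
        assert abs(int(peaks.table["summit"].iloc[0]) - 5_000) <= 1

    def test_recovers_planted_peaks_on_simulation(self, tiny_sim):
        cfg, cat = tiny_sim["config"], tiny_sim["catalog"]
        frags, cells = tiny_sim["frags"], tiny_sim["cells"]
        # doublet barcodes carry exact fragment copies, which would break
        # the Poisson background model; the pipeline removes them upstream
        good = cells[~cells["is_lowq"] & ~cells["is_doublet"]]
        tissue_of = good.set_index("barcode")["tissue"]
        sub = frags[frags["barcode"].isin(set(good["barcode"]))]
        labels = tissue_of.reindex(sub["barcode"]).to_numpy()
        groups = {t: sub[labels == t] for t in tissue_of.unique()}
        called = call_peaks_pseudobulk(groups, list(cfg.genome), width=500)
        truth_summits = ((cat.peaks["start"] + cat.peaks["end"]) // 2)
        recovered = 0
        for chrom, grp in cat.peaks.groupby("chrom"):
            cs = called.table[called.table["chrom"] == chrom]["summit"]
            cs = np.sort(cs.to_numpy())
            ts = ((grp["start"] + grp["end"]) // 2).to_numpy()
            if cs.size == 0:
                continue
            j = np.clip(np.searchsorted(cs, ts), 1, cs.size) - 1
            near = np.minimum(np.abs(cs[j] - ts),
                              np.abs(cs[np.minimum(j + 1, cs.size - 1)] - ts))
            # planted regions have a flat insertion plateau, so the pileup
            # argmax lands anywhere inside: recovery = summit within the
            # planted region (half its width from the center)
            recovered += int((near <= cfg.peak_width_bp // 2).sum())
        assert recovered >= 0.9 * len(cat.peaks)
        # false-call budget: the per-position tail cutoff admits up to
        # pvalue * genome_bp spurious candidates in expectation
        genome_bp = sum(l for _, l in cfg.genome)
        false = 0
        for chrom, grp in called.table.groupby("chrom"):
            ts = np.sort(truth_summits[cat.peaks["chrom"] == chrom].to_numpy())
            cs = grp["summit"].to_numpy()
            j = np.clip(np.searchsorted(ts, cs), 1, ts.size) - 1
            near = np.minimum(np.abs(ts[j] - cs),
                              np.abs(ts[np.minimum(j + 1, ts.size - 1)] - cs))
            false += int((near > 1000).sum())
        assert false <= 1e-4 * genome_bp
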