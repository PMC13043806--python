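# chromtrace

Single-cell chromatin accessibility (scATAC-seq) analysis across multiple
tissues, built around one question: **do shared stromal cell types —
endothelial cells, fibroblasts, macrophages — carry chromatin signatures of
their tissue of origin, strong enough to trace each cell back to its source
organ?**

The package implements the full analysis chain from fragment files to the
tracing readout, together with a seedable synthetic fragment generator that
plants known structure (housekeeping, tissue-level, and cell-type-level
accessible regions; nucleosome-periodic fragment lengths; doublets;
low-quality barcodes; motif footprints), so every stage can be validated as
a parameter-recovery experiment against machine-readable ground truth.

## What it computes

Given fragments (chrom, start, end, barcode, count; 0-based half-open, both
endpoints Tn5 insertion sites):

1. **QC** — per-barcode fragment depth and TSS enrichment (mean insertion
   count at TSS ± 50 bp over the outermost 100 bp flanks of a ± 2 kb
   window); cells with < 1000 fragments or enrichment < 4 are removed.
   Synthetic-doublet k-nearest-neighbor scoring (K = 10) flags and removes
   doublets.
2. **Tile matrix & iterative LSI** — 5-kb bin insertion counts; TF-IDF
   `ln(1 + 10^4 · TF · IDF)` on binarized counts; 4 rounds of truncated SVD
   (30 dims) with coarse-cluster variable-feature re-selection at
   resolutions (0.1, 0.2, 0.4) over 65,000 variable features; components
   with |r| > 0.75 against log depth dropped.
3. **Clustering** — shared-nearest-neighbor graph (k = 30, Jaccard edge
   weights, prune < 1/15), modularity optimization at resolution 1, at most
   60 clusters.
4. **Peaks & markers** — capped (ceiling 4) cells × peaks matrix; Wilcoxon
   group-vs-rest markers (gene scores: FDR ≤ 0.01, log2FC ≥ 1.25; peaks:
   FDR ≤ 0.1, log2FC ≥ 0.5) with Benjamini–Hochberg correction; a minimal
   Poisson pseudobulk peak caller when no peak set is supplied.
5. **Gene activity** — exponential distance decay (5 kb constant, 100 kb
   horizon, 5 kb upstream extension) around gene bodies, depth-normalized;
   kNN imputation.
6. **Similarity & motifs** — Jaccard indices between accessible peak sets
   (peak open in ≥ 5 % of a group's cells); hypergeometric motif enrichment
   in marker peaks (FDR ≤ 0.1, log2FC ≥ 0.1); flank-normalized Tn5
   insertion footprints around motif centers.
7. **Metacells** — kernel archetypal analysis: adaptive Gaussian kernel M
   on the LSI embedding, factorized as M ≈ M·B·A with column-stochastic A
   (archetype weights per cell) and B (cell weights per archetype), 90
   archetypes, waypoint initialization from 10 eigenvectors, Frank–Wolfe
   alternating minimization (ε = 1e-5, 10–50 iterations + 5 refinement
   steps); hard assignment by argmax of A.
8. **Tissue-of-origin tracing** — per-metacell tissue composition;
   chromatin modules from average-linkage clustering of metacell Jaccard
   similarity within each stromal cell type; hypergeometric module–tissue
   association (FDR < 0.05); tissue signatures = tissue-unique peaks of
   associated modules (training cells only); held-out stromal cells
   assigned to the tissue whose signature best matches their binarized
   peak profile (Jaccard argmax).

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic atlas (9 tissues × [endothelial, fibroblast, macrophage,
organ-restricted parenchyma] × 60 cells, ~2,500 fragments/cell) and write
tables under `results/`:

```bash
python analysis/01_simulate.py
...
python analysis/07_trace_origin.py
```

Output of the sequence (seed 1):

```
simulated 2376 barcodes / 6388980 fragments
planted peaks by class: {'tissue': 360, 'celltype': 240, 'housekeeping': 200}
retained 2260 / 2376 barcodes (>=1000 fragments and TSS enrichment >= 4)
low-quality excluded: 100.0%; normal retained: 99.6%
36 clusters over 2114 cells (102 doublet barcodes removed before embedding)
adjusted Rand index vs planted (tissue x cell type): 0.999
mean recall 1.000, mean precision 1.000            # marker peaks vs truth
intra-type Jaccard: stromal mean 0.711 (max 0.717)
    vs organ-restricted mean 0.919 (min 0.890)
Klf1 footprint in endothelial: center/flank 0.512 (planted 0.50)
90 distinct metacell ids over 2114 cells
tissue purity: median 1.000, 98.9% of metacells >= 0.8
held-out stromal cells: 787; called: 99.4%
tissue-of-origin accuracy (among called): 0.968
```

Reading the numbers: QC separates planted low-quality barcodes perfectly;
clustering recovers the 36 planted (tissue, cell-type) populations; marker
detection at the published thresholds recovers exactly the truth-expected
marker peaks; shared stromal types show *lower* intra-type accessibility
similarity than organ-restricted types (they straddle nine different
tissue-peak programs); the aggregate footprint dip matches the planted
insertion-depletion factor (0.5); the metacell stage yields exactly 90
metacells, almost all tissue-pure; and held-out stromal cells trace back
to their source tissue ~97 % of the time — the headline claim, recovered
as a parameter-recovery experiment. With the tissue-level peaks removed
from the generator, the same pipeline cannot classify stromal cells at
better than chance.

A pipeline run on a config file is also available from the shell:

```bash
chromtrace all --config cfg.toml --outdir run/   # or any stage prefix
```

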