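# Methods

This note documents the models and procedures implemented in `chromtrace`,
the defaults and why they were chosen, what the synthetic data generator
does and does not emulate, and the numerical choices a maintainer would
want written down.

## Counting convention

Every fragment record (chrom, start, end, barcode, count; 0-based
half-open) contributes two Tn5 insertion events, at `start` and `end - 1`;
endpoints are assumed already Tn5-shifted (the 10x convention). Tiles,
peaks, TSS profiles and footprints all count insertions, never fragment
overlaps, so a fragment spanning a boundary splits across features. This
single convention avoids subtle double-counting disagreements between
stages.

## Synthetic data generator

The generator emulates the structure of a multi-tissue scATAC atlas in
which stromal cell types are shared across organs:

* **Populations.** `n_tissues` = 9 tissues; per tissue, three shared
  stromal types (endothelial, fibroblast, macrophage analogues) plus one
  organ-restricted parenchymal type; 60 cells per (tissue, type) by
  default (2,160 singlets).
* **Peak classes.** 200 housekeeping peaks (open everywhere), 40 tissue
  peaks per tissue (open in every cell of that tissue regardless of type —
  the tissue-of-origin signal), 20 cell-type peaks per type (open in that
  type in every tissue). Tissue peaks deliberately outnumber per-type
  peaks: the study system this emulates reported tissue-specific peak
  counts in shared cell types an order of magnitude above per-type marker
  scales, and the tissue-level module structure the tracing analysis
  recovers presumes exactly this dominance.
* **Peak width 1000 bp.** A footprint profile is normalized by its
  ±[200, 250] bp flank band. If planted regions were only 500 bp wide that
  band would sit on the region boundary, where insertion density tapers
  for purely geometric reasons (fragment midpoints are uniform inside the
  region, so endpoints thin out near its edge), biasing the depletion
  estimate upward by ~0.35. At 1000 bp the whole ±250 bp window lies in
  the flat interior and the footprint readout measures the planted
  depletion factor alone.
* **Genome 5 × 30 Mb.** A mini-genome, scaled so that the probability a
  cell deposits a stray background fragment in any one closed peak
  (~0.3 % at default depth) matches real libraries. On a much smaller
  genome this contamination rate becomes tens of times too high and
  accessible-set analyses drown in background — an artifact of scale, not
  of the method.
* **Depth and fragment length.** Per-cell fragment counts are lognormal
  (median 2,500, σ = 0.35) so nearly all normal cells clear the
  1000-fragment QC floor; lengths are a 70/30 mixture of N(75, 15) and
  N(220, 30) truncated to [20, 600] — the nucleosome-free /
  mono-nucleosome pattern QC plots expect.
* **TSS enrichment** arises mechanistically: housekeeping and cell-type
  peaks carry a paired gene whose TSS sits at the peak center, so signal
  fragments concentrate insertions near TSSs. Low-quality barcodes draw
  300–800 background-only fragments and therefore fail both QC thresholds.
* **Doublets** are unions of two real cells' fragment sets under a fresh
  barcode (5 % rate), mirroring how a real doublet accumulates both cells'
  fragments.
* **Footprints.** Motifs are planted at the centers of chosen peak
  classes (defaults: a Klf1-like motif in endothelial peaks, a Runx1-like
  motif in macrophage peaks). Insertions falling within ±10 bp of a motif
  center are thinned by the depletion factor (default 0.5) — but only for
  cells whose chromatin is open at that peak, since a transcription factor
  leaves a footprint only where it is bound. This makes the center dip
  group-specific, which is the claim structure the footprint analysis
  tests.

**What the generator does not emulate:** sequence content (motif hits are
planted coordinates, no FASTA), Tn5 sequence bias, GC bias, batch effects,
copy-number variation, gradients/continuous differentiation trajectories,
and peak-width heterogeneity. Passing tests therefore demonstrate that the
pipeline recovers planted discrete population structure at realistic
sparsity — not that it is robust to these additional real-data phenomena.

## QC

TSS enrichment = mean insertion count over TSS ± 50 bp divided by the mean
over the outermost 100 bp of each ± 2 kb flank (ε = 0.1 guards empty
flanks). The exact formula follows the convention of the standard scATAC
toolkits; only the threshold (4) is prescribed, as is the 1000-fragment
floor. Boundary values are retained.

Doublet scoring synthesizes one artificial doublet per real cell by
summing random distinct cell pairs' tile counts, projects everything into
a provisional (single-round) LSI basis, and scores each cell by the
fraction of synthetic barcodes among its K = 10 nearest neighbors,
normalized by the synthetic prior. Cells scoring ≥ 1 (more synthetic
neighbors than chance) are removed before the final embedding; at the
default scale this removes ~95 % of planted doublets at a ~2 % singlet
cost. Note the discrimination is underpowered below a few hundred cells;
`qc.doublet_threshold = None` disables removal.

## Embedding and clustering

TF-IDF: binarize, TF = row-normalized binary counts, IDF =
`ln(1 + n_cells / (1 + n_cells_with_feature))`, X = `ln(1 + 10^4·TF·IDF)`
(the "log_tfidf_v1" variant; the exact formula is a convention choice
among LSI implementations). Truncated SVD via ARPACK with a fixed start
vector for determinism; basis column signs fixed by making each column's
largest-magnitude entry positive. Components correlating with log depth
beyond |r| = 0.75 are dropped.

Iterative LSI: round 1 selects top features by total count; rounds 2–4
cluster the previous embedding at resolutions 0.1/0.2/0.4, form
per-cluster pseudobulks (counts-per-10k, log1p), and re-select the top
features by cross-cluster variance. Fewer than two clusters at any round
carries the feature set forward unchanged.

SNN clustering: kNN graph (k = 30), edges weighted by neighbor-set Jaccard
overlap, pruned below 1/15, Leiden modularity optimization
(RBConfiguration, fixed seed) at resolution 1; if more than 60 clusters
result, the smallest is merged into its nearest-centroid neighbor until
the cap holds. Modularity at resolution 1 may subdivide large homogeneous
blobs; subdivisions are pure and mergeable, which is why tests assert
purity and the capped count rather than an exact cluster number.

Batch adjustment is a per-dimension location/scale match (batch mean and
SD mapped to pooled), an intentionally simple substitute for dedicated
integration algorithms; with a single batch it is the identity. This is a
documented fidelity gap, not an equivalent of Harmony-style integration.

## Markers and motifs

Group-vs-rest Wilcoxon rank-sum per feature: exact enumeration for pooled
n ≤ 12 without ties, otherwise a tie- and continuity-corrected normal
approximation (vectorized across features). log2FC uses pseudocount 0.1 on
group means; BH adjustment runs within each group across features. The
exhaustive oracle puts the approximation within 0.031 of exact p at
4 + 4 samples, shrinking with n — small-sample p-values near a threshold
should use the exact path.

Motif enrichment: hypergeometric upper tail of motif-bearing peaks among a
group's marker peaks versus the peak universe, BH across motifs,
significance at FDR ≤ 0.1 and log2FC ≥ 0.1. The default motif mode uses
planted coordinates; a log-odds PWM scanner over supplied sequences (both
strands, threshold = 0.8 × max achievable score) covers real data. No Tn5
sequence-bias correction is applied to footprints — flank normalization
only, with a pseudocount of 1 on the flank sum.

## Metacells (kernel archetypal analysis)

Kernel: k = 15 nearest neighbors, adaptive bandwidth σ_i = distance to the
⌈k/3⌉-th neighbor, affinity `exp(-d²/(σ_i σ_j))` on the union of kNN
edges, symmetrized by the maximum; diagonal 1.

Fit: minimize ‖M − M·B·A‖²_F with columns of A (90 × n) and B (n × 90) on
the probability simplex. B starts one-hot at waypoint cells — extrema of
the top 10 eigenvectors of the symmetrically degree-normalized kernel,
topped up by greedy max–min distance selection — and A uniform. Each outer
iteration runs 20 Frank–Wolfe steps on A (the problem is separable per
cell) then 20 on B, each with exact line search clamped to [0, 1], so the
objective is non-increasing by construction and both matrices stay exactly
on the simplex. Convergence: relative objective change < 1e-5 after ≥ 10
iterations, cap 50, then 5 further refinement iterations (implemented as
ordinary iterations post-convergence). Empty archetypes are retained as
ids and flagged, keeping the configured count contract exact. ARPACK
failures in the waypoint eigendecomposition fall back to the partially
converged eigenvectors — waypoints only need approximate extrema.

## Tissue-of-origin tracing

Tissue composition F(m, t) = fraction of metacell m's cells from tissue t.
Modules are detected **within each stromal cell type** (metacells whose
majority type is that type): average-linkage clustering of 1 − Jaccard
between metacell accessible sets, cut into one module per tissue present,
with hypergeometric over-representation of tissue-majority metacells per
(module, tissue) and BH control at FDR < 0.05. Detecting modules globally
instead lets the strong cross-tissue similarity of shared cell types chain
different tissues' metacells into mixed modules; the per-type design
matches how tissue-specific modules are read out in shared populations.

Signatures: for each tissue, the union of its associated modules'
accessible sets, where a module's set is computed over the pooled training
cells of its member metacells (pooling makes the ≥ 5 % accessibility
threshold meaningful against stray background hits). Peaks claimed by more
than one tissue's signature — housekeeping and shared cell-type programs —
carry no origin information and are stripped, leaving tissue-unique peaks;
on synthetic truth the signatures then essentially coincide with the
planted tissue peaks. A tissue with no associated module falls back to its
significantly differential peaks versus the rest (capped at 500; if
nothing is significant the top-ranked peaks are used, which on null data
produces chance-level signatures).

Prediction: a held-out cell's binarized peak profile is scored against
each signature by Jaccard; argmax wins, ties abstain. Training/test is a
seeded 50/50 split; signatures never see test cells (the metacell
geometry is fit on all cells, but signatures are peak sets computed from
training members only). Accuracy is reported over called cells; the
chance-level control (no tissue peaks planted) yields zero-score ties for
stromal cells — no call — so its correct-classification fraction sits at
or below the 1/9 chance level.

## Problem sizes

The default study conditions (2,160 singlets + doublets + low-quality
barcodes, ~6.4 M fragments, 800 peaks on a 150 Mb mini-genome) run the
full pipeline in ~2 minutes on one CPU; the chance-level control uses 30
cells per type at ~2,000 fragments/cell. Unit tests use a 3-tissue,
225-cell configuration of the same structure.

## Known limitations

* The peak caller is a minimal Poisson summit caller (genome-wide mean
  rate, no local lambda, no FDR on calls); by design the pipeline can
  bypass it (`peak.source = "truth"`) so caller error does not confound
  downstream analyses. Its per-position tail cutoff admits up to
  1e-4 × genome_bp spurious candidates in expectation.
* Group-vs-rest marker testing does not use bias-matched background cells.
* Batch adjustment is moment matching, not integration.
* Doublet removal is threshold-based and underpowered at small cell
  counts.
* The tracing readout assumes discrete tissues and cell types; mixtures,
  gradients, or migration between organs are out of scope.
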