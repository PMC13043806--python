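"""Stage orchestration: simulate -> QC -> tiles -> embed -> ... -> trace.

Stages run as a contiguous prefix of the full list, each consuming the
in-memory context produced by its predecessors and (in ``run_pipeline``)
persisting its outputs under the run directory.  Every stage logs the
thresholds it consumed so a run's parameters are auditable.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import qc as qc_mod
from .config import PipelineConfig, load_config
from .differential import marker_features
from .embed import batch_adjust, iterative_lsi, snn_cluster
from .features import PeakSet, call_peaks_pseudobulk, make_peak_matrix, \
    make_tile_matrix
from .genes import gene_scores, impute_scores
from .io import write_fragments_df, write_matrix
from .metacells import assign_metacells, build_kernel, fit_archetypes, \
    init_waypoints
from .motifs import footprint, motif_enrichment, planted_hits
from .similarity import accessible_set, detect_modules, intra_type_similarity, \
    jaccard_matrix
from .simulate import SimConfig, build_truth, simulate_fragments, write_truth
from .tracing import build_tissue_signatures, celltype_metacell_correlation, \
    holdout_split, prediction_accuracy, predict_origin, tissue_composition

log = logging.getLogger(__name__)

STAGES = ["simulate", "qc", "tiles", "embed", "cluster", "peaks",
          "genescores", "markers", "jaccard", "motifs", "metacells", "trace"]


def _stage_simulate(ctx: dict) -> None:
    sim: SimConfig = ctx["sim_config"]
    catalog = build_truth(sim)
    frags, cells = simulate_fragments(catalog, sim)
    ctx["catalog"] = catalog
    ctx["cells"] = cells
    ctx["frags"] = frags
    ctx["genome"] = list(sim.genome)
    log.info("simulate: %d cells, %d fragments, %d planted peaks",
             len(cells), len(frags), catalog.n_peaks)


def _stage_qc(ctx: dict) -> None:
    cfg: PipelineConfig = ctx["config"]
    tss = ctx["catalog"].tss_table()
    metrics = qc_mod.qc_metrics(ctx["frags"], tss, ctx["genome"], cfg)
    retained = qc_mod.filter_cells(metrics, cfg)
    ctx["qc_metrics"] = metrics
    ctx["retained"] = retained
    log.info("qc: thresholds min_fragments=%d min_tss_enrichment=%.2f; "
             "%d/%d barcodes retained", cfg.qc.min_fragments,
             cfg.qc.min_tss_enrichment, len(retained), len(metrics))


def _stage_tiles(ctx: dict) -> None:
    cfg: PipelineConfig = ctx["config"]
    ctx["tile_matrix"] = make_tile_matrix(
        ctx["frags"], ctx["genome"], tile_bp=cfg.tiles.size_bp,
        barcodes=ctx["retained"])
    log.info("tiles: size_bp=%d -> %s matrix", cfg.tiles.size_bp,
             ctx["tile_matrix"].shape)


def _stage_embed(ctx: dict) -> None:
    cfg: PipelineConfig = ctx["config"]
    # provisional single-round LSI for synthetic-doublet projection
    from .embed import svd_embed, tfidf_transform
    from .embed import LSIModel
    tm = ctx["tile_matrix"]
    totals = np.asarray(tm.counts.sum(axis=0)).ravel()
    n_var = min(cfg.lsi.n_variable_features, tm.shape[1])
    feat0 = np.sort(np.argsort(totals)[::-1][:n_var])
    X0, idf0 = tfidf_transform(tm.counts, feat0)
    _, basis0, kept0 = svd_embed(X0, tm.depth, cfg.lsi.n_dims,
                                 cfg.lsi.depth_cor_cutoff, seed=cfg.seed)
    model0 = LSIModel(feat0, idf0, basis0, np.zeros(basis0.shape[1]),
                      kept0, tm.shape[0])
    scores = qc_mod.doublet_enrichment(tm, model0, k=cfg.qc.doublet_k,
                                       seed=cfg.seed)
    metrics = ctx["qc_metrics"].set_index("barcode")
    metrics["doublet_enrichment"] = scores
    ctx["qc_metrics"] = metrics.reset_index()
    if cfg.qc.doublet_threshold is not None:
        keep = [b for b in tm.barcodes
                if scores.get(b, 0.0) < cfg.qc.doublet_threshold]
        n_removed = tm.shape[0] - len(keep)
        if n_removed:
            log.info("embed: removed %d putative doublets at enrichment >= %s",
                     n_removed, cfg.qc.doublet_threshold)
            tm = tm.subset_cells(keep)
            ctx["tile_matrix"] = tm
            ctx["retained"] = keep
    model, emb = iterative_lsi(tm, cfg.lsi, cfg.cluster, seed=cfg.seed)
    emb = batch_adjust(emb, np.zeros(len(emb.barcodes)))  # single batch
    ctx["lsi_model"] = model
    ctx["embedding"] = emb
    log.info("embed: %d LSI iterations, resolutions %s, %d variable features,"
             " %d dims (%d kept); doublet K=%d", cfg.lsi.iterations,
             list(cfg.lsi.resolutions), cfg.lsi.n_variable_features,
             cfg.lsi.n_dims, int(model.kept_dims.sum()), cfg.qc.doublet_k)


def _stage_cluster(ctx: dict) -> None:
    cfg: PipelineConfig = ctx["config"]
    ctx["clusters"] = snn_cluster(ctx["embedding"], cfg.cluster, seed=cfg.seed)
    log.info("cluster: k.param=%d resolution=%s maxClusters=%d -> %d clusters",
             cfg.cluster.k_param, cfg.cluster.resolution,
             cfg.cluster.max_clusters, ctx["clusters"].nunique())


def _stage_peaks(ctx: dict) -> None:
    cfg: PipelineConfig = ctx["config"]
    if cfg.peak.source == "truth":
        peakset = PeakSet.from_truth(ctx["catalog"].peaks)
    else:
        frags = ctx["frags"]
        clusters = ctx["clusters"]
        labels = clusters.reindex(frags["barcode"]).to_numpy()
        groups = {str(c): frags[labels == c]
                  for c in clusters.unique()}
        peakset = call_peaks_pseudobulk(groups, ctx["genome"],
                                        width=cfg.peak.width_bp,
                                        pvalue=cfg.peak.pvalue)
    ctx["peakset"] = peakset
    ctx["peak_matrix"] = make_peak_matrix(
        ctx["frags"], peakset, ctx["genome"], ceiling=cfg.peak.ceiling,
        barcodes=ctx["retained"])
    log.info("peaks: source=%s ceiling=%d -> %d peaks", cfg.peak.source,
             cfg.peak.ceiling, len(peakset))


def _stage_genescores(ctx: dict) -> None:
    cfg: PipelineConfig = ctx["config"]
    genes = ctx["catalog"].genes
    raw = gene_scores(ctx["tile_matrix"], genes,
                      decay_bp=cfg.genescore.decay_bp,
                      max_dist_bp=cfg.genescore.max_dist_bp,
                      upstream_ext_bp=cfg.genescore.upstream_ext_bp)
    ctx["gene_scores_raw"] = raw
    ctx["gene_scores"] = impute_scores(raw, ctx["embedding"].coords,
                                       k=cfg.genescore.impute_k)
    log.info("genescores: decay=%s max_dist=%s imputed with k=%d",
             cfg.genescore.decay_bp, cfg.genescore.max_dist_bp,
             cfg.genescore.impute_k)


def _cell_labels(ctx: dict, column: str) -> pd.Series:
    cells = ctx["cells"].set_index("barcode")
    return cells[column]


def _stage_markers(ctx: dict) -> None:
    cfg: PipelineConfig = ctx["config"]
    types = _cell_labels(ctx, "cell_type")
    gm = ctx["gene_scores"]
    ctx["markers_genes"] = marker_features(
        gm, types.reindex(gm.barcodes).to_numpy(), cfg.markers_genes)
    pm = ctx["peak_matrix"]
    ctx["markers_peaks"] = marker_features(
        pm, types.reindex(pm.barcodes).to_numpy(), cfg.markers_peaks)
    log.info("markers: genes FDR<=%s log2FC>=%s; peaks FDR<=%s log2FC>=%s",
             cfg.markers_genes.fdr, cfg.markers_genes.log2fc,
             cfg.markers_peaks.fdr, cfg.markers_peaks.log2fc)


def _stage_jaccard(ctx: dict) -> None:
    cfg: PipelineConfig = ctx["config"]
    pm = ctx["peak_matrix"]
    types = _cell_labels(ctx, "cell_type").reindex(pm.barcodes)
    bmap = {b: i for i, b in enumerate(pm.barcodes)}
    sets = []
    for ct in sorted(types.dropna().unique()):
        rows = np.array([bmap[b] for b in types.index[types == ct]])
        sets.append(accessible_set(pm, rows, ct, cfg.similarity.min_fraction))
    ctx["celltype_jaccard"] = jaccard_matrix(sets)
    cells = ctx["cells"][ctx["cells"]["barcode"].isin(bmap)]
    ctx["intra_type_jaccard"] = intra_type_similarity(
        pm, cells, min_fraction=cfg.similarity.min_fraction,
        min_cells=cfg.similarity.min_cells, seed=cfg.seed)
    log.info("jaccard: min_fraction=%s over %d cell types",
             cfg.similarity.min_fraction, len(sets))


def _stage_motifs(ctx: dict) -> None:
    cfg: PipelineConfig = ctx["config"]
    hits = planted_hits(ctx["catalog"].peaks)
    ctx["motif_hits"] = hits
    pm = ctx["peak_matrix"]
    all_peaks = set(ctx["peakset"].table["peak_id"])
    # map matrix feature labels back to peak ids for the marker sets
    label_to_id = dict(zip(pm.features, ctx["peakset"].table["peak_id"]))
    tables = []
    markers = ctx["markers_peaks"]
    for ct, grp in markers[markers["passes"]].groupby("group"):
        marker_ids = {label_to_id[f] for f in grp["feature"]}
        if not marker_ids:
            continue
        t = motif_enrichment(hits, marker_ids, all_peaks,
                             fdr_threshold=cfg.motif.fdr,
                             log2fc_threshold=cfg.motif.log2fc)
        t.insert(0, "group", ct)
        tables.append(t)
    ctx["motif_enrichment"] = pd.concat(tables, ignore_index=True) \
        if tables else pd.DataFrame()
    types = _cell_labels(ctx, "cell_type")
    retained = set(ctx["retained"])
    types = types[types.index.isin(retained)]
    profiles = []
    for motif in hits["motif"].unique():
        prof = footprint(ctx["frags"][ctx["frags"]["barcode"].isin(retained)],
                         hits[hits["motif"] == motif], ctx["genome"], types,
                         flank=cfg.motif.footprint_flank,
                         norm_band=(cfg.motif.footprint_norm_lo,
                                    cfg.motif.footprint_norm_hi))
        prof.insert(0, "motif", motif)
        profiles.append(prof)
    ctx["footprints"] = pd.concat(profiles, ignore_index=True) \
        if profiles else pd.DataFrame()
    log.info("motifs: FDR<=%s log2FC>=%s; %d motifs footprinted",
             cfg.motif.fdr, cfg.motif.log2fc, hits["motif"].nunique())


def _stage_metacells(ctx: dict) -> None:
    cfg: PipelineConfig = ctx["config"]
    emb = ctx["embedding"]
    kernel = build_kernel(emb.coords, k=cfg.metacells.kernel_k)
    init = init_waypoints(kernel, emb.coords, n_archetypes=cfg.metacells.n,
                          n_waypoint_eigs=cfg.metacells.n_waypoint_eigs,
                          seed=cfg.seed)
    model = fit_archetypes(kernel, init,
                           epsilon=cfg.metacells.convergence_epsilon,
                           min_iter=cfg.metacells.min_iter,
                           max_iter=cfg.metacells.max_iter,
                           refine_iter=cfg.metacells.refine_iter)
    pm = ctx["peak_matrix"].subset_cells(emb.barcodes)
    ctx["kernel"] = kernel
    ctx["archetype_model"] = model
    ctx["metacell_assignment"] = assign_metacells(model, pm)
    log.info("metacells: n=%d n_waypoint_eigs=%d epsilon=%s min_iter=%d "
             "max_iter=%d -> %d assigned ids (converged=%s after %d iters)",
             cfg.metacells.n, cfg.metacells.n_waypoint_eigs,
             cfg.metacells.convergence_epsilon, cfg.metacells.min_iter,
             cfg.metacells.max_iter,
             ctx["metacell_assignment"].n_assigned_ids,
             model.converged, model.iterations)


def _stage_trace(ctx: dict) -> None:
    cfg: PipelineConfig = ctx["config"]
    assignment = ctx["metacell_assignment"]
    pm = ctx["peak_matrix"].subset_cells(ctx["embedding"].barcodes)
    tissue_of = _cell_labels(ctx, "tissue")
    type_of = _cell_labels(ctx, "cell_type")

    composition = tissue_composition(assignment, tissue_of)
    ctx["tissue_composition"] = composition
    ctx["celltype_metacell_r"] = celltype_metacell_correlation(
        assignment, pm, type_of.reindex(pm.barcodes))

    train, test = holdout_split(list(pm.barcodes),
                                fraction=cfg.tracing.holdout_fraction,
                                seed=cfg.seed)
    train_set = set(train)
    bmap = {b: i for i, b in enumerate(pm.barcodes)}
    # module structure is discovered from full metacell memberships; only
    # signature building and prediction respect the train/test split
    meta_sets: dict[int, object] = {}
    majority = {}
    majority_type = {}
    for m, grp in assignment.cells.groupby("metacell"):
        members = list(grp["barcode"])
        rows = np.array([bmap[b] for b in members])
        meta_sets[m] = accessible_set(pm, rows, str(m),
                                      cfg.similarity.min_fraction)
        majority[m] = tissue_of.reindex(members).mode().iloc[0]
        majority_type[m] = type_of.reindex(members).mode().iloc[0]
    labels = sorted(meta_sets)
    sim_mat = jaccard_matrix([meta_sets[m] for m in labels])
    sim_mat.index = sim_mat.columns = labels
    majority_s = pd.Series(majority).reindex(labels)
    majority_type_s = pd.Series(majority_type).reindex(labels)
    ctx["metacell_jaccard"] = sim_mat
    ctx["metacell_majority_tissue"] = majority_s
    ctx["metacell_majority_type"] = majority_type_s

    # stromal = cell types observed in more than one tissue; modules and
    # tissue signatures are built within each stromal type, mirroring the
    # per-cell-type module analysis, so shared-type similarity cannot chain
    # different tissues' metacells together
    cells = ctx["cells"]
    spread = cells.groupby("cell_type")["tissue"].nunique()
    stromal_types = set(spread.index[spread > 1])
    ctx["stromal_types"] = stromal_types
    meta_of = assignment.cells.set_index("barcode")["metacell"]

    modules_by_type: dict[str, object] = {}
    signatures_by_type: dict[str, dict[str, frozenset[str]]] = {}
    for ct in sorted(stromal_types):
        ct_metas = [m for m in labels if majority_type_s.loc[m] == ct]
        ct_train = [b for b in train if type_of.get(b) == ct]
        if len(ct_metas) < 2 or not ct_train:
            log.warning("stromal type %s lacks metacells for tracing", ct)
            continue
        sub_sim = sim_mat.loc[ct_metas, ct_metas]
        n_modules = min(int(tissue_of.reindex(ct_train).nunique()),
                        len(ct_metas))
        modules = detect_modules(sub_sim, majority_s.loc[ct_metas], n_modules,
                                 fdr_threshold=cfg.tracing.module_fdr)
        modules_by_type[ct] = modules
        module_sets: dict[int, object] = {}
        for mod in np.unique(modules.assignment):
            meta_ids = set(modules.assignment.index[
                modules.assignment == mod])
            members = [b for b in ct_train if meta_of.get(b) in meta_ids]
            if not members:
                continue
            rows = np.array([bmap[b] for b in members])
            module_sets[mod] = accessible_set(pm, rows, f"{ct}|module{mod}",
                                              cfg.similarity.min_fraction)
        ct_train_pm = pm.subset_cells(ct_train)
        signatures_by_type[ct] = build_tissue_signatures(
            modules, module_sets,
            peak_matrix=ct_train_pm,
            tissue_of=tissue_of.reindex(ct_train),
            fallback_top=cfg.tracing.fallback_top_peaks,
            marker_cfg=cfg.markers_peaks)
    ctx["modules"] = modules_by_type
    ctx["tissue_signatures"] = signatures_by_type

    pred_frames = []
    for ct, signatures in signatures_by_type.items():
        test_ct = [b for b in test if type_of.get(b) == ct]
        if not test_ct:
            continue
        preds = predict_origin(pm.subset_cells(test_ct), signatures)
        preds.insert(1, "cell_type", ct)
        pred_frames.append(preds)
    if not pred_frames:
        raise ValueError("no stromal cells available for origin prediction")
    preds = pd.concat(pred_frames, ignore_index=True)
    acc = prediction_accuracy(preds, tissue_of)
    preds["true_tissue"] = tissue_of.reindex(preds["barcode"]).to_numpy()
    ctx["origin_predictions"] = preds
    ctx["origin_accuracy"] = acc
    log.info("trace: signatures for %d stromal types, held-out stromal "
             "accuracy %.3f over %d cells", len(signatures_by_type), acc,
             len(preds))


_STAGE_FN = {
    "simulate": _stage_simulate, "qc": _stage_qc, "tiles": _stage_tiles,
    "embed": _stage_embed, "cluster": _stage_cluster, "peaks": _stage_peaks,
    "genescores": _stage_genescores, "markers": _stage_markers,
    "jaccard": _stage_jaccard, "motifs": _stage_motifs,
    "metacells": _stage_metacells, "trace": _stage_trace,
}


def sim_config_from_dict(data: dict, seed: int | None = None) -> SimConfig:
    names = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(data) - names
    if unknown:
        raise KeyError(f"unknown sim configuration keys: {sorted(unknown)}")
    kwargs = dict(data)
    for key in ("cell_types_per_tissue", "fraglen_weights"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    if "genome" in kwargs:
        kwargs["genome"] = tuple((c, int(l)) for c, l in kwargs["genome"])
    if "fraglen_components" in kwargs:
        kwargs["fraglen_components"] = tuple(
            (float(a), float(b)) for a, b in kwargs["fraglen_components"])
    if "frags_per_cell_lognormal" in kwargs:
        kwargs["frags_per_cell_lognormal"] = tuple(
            kwargs["frags_per_cell_lognormal"])
    if "lowq_frag_range" in kwargs:
        kwargs["lowq_frag_range"] = tuple(kwargs["lowq_frag_range"])
    if seed is not None:
        kwargs["seed"] = seed
    return SimConfig(**kwargs)


def run_stages(sim_config: SimConfig, config: PipelineConfig,
               stages: list[str] | None = None) -> dict:
    """Run a contiguous stage prefix in memory; returns the context dict."""
    stages = stages or STAGES
    if stages != STAGES[: len(stages)]:
        missing = STAGES[: STAGES.index(stages[0])]
        raise ValueError(
            f"stages must be a contiguous prefix of {STAGES}; "
            f"run {missing} first" if missing else
            f"stages must be a contiguous prefix of {STAGES}")
    ctx = {"sim_config": sim_config, "config": config}
    for stage in stages:
        _STAGE_FN[stage](ctx)
    return ctx


def _persist(ctx: dict, stage: str, outdir: Path) -> None:
    sdir = outdir
    sdir.mkdir(parents=True, exist_ok=True)
    if stage == "simulate":
        write_fragments_df(ctx["frags"], sdir / "fragments.tsv.gz")
        write_truth(ctx["catalog"], ctx["cells"], sdir)
    elif stage == "qc":
        ctx["qc_metrics"].to_csv(sdir / "qc_metrics.tsv", sep="\t", index=False)
        pd.Series(ctx["retained"], name="barcode").to_csv(
            sdir / "retained_barcodes.tsv", sep="\t", index=False)
    elif stage == "tiles":
        write_matrix(ctx["tile_matrix"], sdir / "tile_matrix")
    elif stage == "embed":
        emb = ctx["embedding"]
        pd.DataFrame(emb.coords, index=emb.barcodes).to_csv(
            sdir / "embedding.tsv", sep="\t")
        ctx["qc_metrics"].to_csv(sdir / "qc_metrics.tsv", sep="\t", index=False)
    elif stage == "cluster":
        ctx["clusters"].rename_axis("barcode").to_frame().to_csv(
            sdir / "clusters.tsv", sep="\t")
    elif stage == "peaks":
        ctx["peakset"].table.to_csv(sdir / "peaks.bed", sep="\t",
                                    header=False, index=False)
        write_matrix(ctx["peak_matrix"], sdir / "peak_matrix")
    elif stage == "genescores":
        write_matrix(ctx["gene_scores"], sdir / "gene_scores")
    elif stage == "markers":
        ctx["markers_genes"].to_csv(sdir / "markers_genes.tsv", sep="\t",
                                    index=False)
        ctx["markers_peaks"].to_csv(sdir / "markers_peaks.tsv", sep="\t",
                                    index=False)
    elif stage == "jaccard":
        ctx["celltype_jaccard"].to_csv(sdir / "celltype_jaccard.tsv", sep="\t")
        ctx["intra_type_jaccard"].rename_axis("cell_type").to_frame().to_csv(
            sdir / "intra_type_jaccard.tsv", sep="\t")
    elif stage == "motifs":
        ctx["motif_enrichment"].to_csv(sdir / "motif_enrichment.tsv",
                                       sep="\t", index=False)
        ctx["footprints"].to_csv(sdir / "footprints.tsv", sep="\t", index=False)
    elif stage == "metacells":
        ctx["metacell_assignment"].cells.to_csv(
            sdir / "metacell_assignment.tsv", sep="\t", index=False)
        pd.Series(ctx["archetype_model"].objective_trace,
                  name="objective").to_csv(sdir / "objective_trace.tsv",
                                           sep="\t", index=False)
    elif stage == "trace":
        ctx["tissue_composition"].to_csv(sdir / "tissue_composition.tsv",
                                         sep="\t")
        ctx["origin_predictions"].to_csv(sdir / "origin_predictions.tsv",
                                         sep="\t", index=False)
        sig = pd.DataFrame(
            [(ct, t, p)
             for ct, sigs in ctx["tissue_signatures"].items()
             for t, peaks in sigs.items() for p in sorted(peaks)],
            columns=["cell_type", "tissue", "peak_id"])
        sig.to_csv(sdir / "tissue_signatures.tsv", sep="\t", index=False)
        pd.DataFrame({"origin_accuracy": [ctx["origin_accuracy"]]}).to_csv(
            sdir / "origin_accuracy.tsv", sep="\t", index=False)


def run_pipeline(config_path: str | Path, outdir: str | Path | None = None,
                 seed: int | None = None,
                 stages: list[str] | None = None) -> dict:
    """Run the configured stage prefix and persist every stage's outputs."""
    config, extras = load_config(config_path)
    if seed is not None:
        config.seed = seed
    pipe_extra = extras.get("pipeline", {})
    outdir = Path(outdir or pipe_extra.get("outdir", "chromtrace_run"))
    stages = stages or pipe_extra.get("stages", STAGES)
    sim_config = sim_config_from_dict(extras.get("sim", {}), seed=config.seed)
    ctx = {"sim_config": sim_config, "config": config}
    if stages != STAGES[: len(stages)]:
        raise ValueError(f"stages must be a contiguous prefix of {STAGES}")
    for stage in stages:
        _STAGE_FN[stage](ctx)
        _persist(ctx, stage, outdir)
    return ctx
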