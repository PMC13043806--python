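"""Pipeline and simulation configuration.

``PipelineConfig`` is the single home for every tunable the pipeline consumes:
QC thresholds, tile size, iterative-LSI settings, clustering parameters,
marker/motif cut-offs, peak-matrix ceiling, and the metacell (kernel
archetypal analysis) parameters.  Stages read their thresholds from here and
echo them to the log so a run's parameters are auditable.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any


@dataclass
class QCConfig:
    min_fragments: int = 1000
    min_tss_enrichment: float = 4.0
    doublet_k: int = 10
    #: cells scoring at or above this synthetic-doublet enrichment (observed
    #: synthetic-neighbor fraction over the synthetic prior) are removed after
    #: scoring; None disables removal
    doublet_threshold: float | None = 1.0
    tss_window_bp: int = 2000
    tss_center_bp: int = 50
    tss_flank_bp: int = 100
    tss_eps: float = 0.1


@dataclass
class TileConfig:
    size_bp: int = 5000


@dataclass
class LSIConfig:
    iterations: int = 4
    resolutions: tuple[float, ...] = (0.1, 0.2, 0.4)
    n_variable_features: int = 65000
    n_dims: int = 30
    depth_cor_cutoff: float = 0.75
    formula: str = "log_tfidf_v1"

    def validate(self) -> None:
        if len(self.resolutions) != self.iterations - 1:
            raise ValueError(
                f"lsi.resolutions must have length iterations-1 "
                f"({self.iterations - 1}), got {len(self.resolutions)}"
            )


@dataclass
class ClusterConfig:
    k_param: int = 30
    resolution: float = 1.0
    max_clusters: int = 60
    snn_prune: float = 1.0 / 15.0


@dataclass
class MarkerConfig:
    fdr: float
    log2fc: float
    pseudocount: float = 0.1


@dataclass
class PeakConfig:
    ceiling: int = 4
    width_bp: int = 500
    source: str = "truth"  # "truth" | "called"
    pvalue: float = 1e-4


@dataclass
class MotifConfig:
    fdr: float = 0.1
    log2fc: float = 0.1
    threshold_frac: float = 0.8
    footprint_flank: int = 250
    footprint_norm_lo: int = 200
    footprint_norm_hi: int = 250


@dataclass
class GeneScoreConfig:
    decay_bp: float = 5000.0
    max_dist_bp: float = 100000.0
    upstream_ext_bp: int = 5000
    impute_k: int = 15


@dataclass
class AnnotateConfig:
    tss_window_bp: int = 3000


@dataclass
class MetacellConfig:
    n: int = 90
    n_waypoint_eigs: int = 10
    convergence_epsilon: float = 1e-5
    min_iter: int = 10
    max_iter: int = 50
    refine_iter: int = 5
    kernel_k: int = 15


@dataclass
class SimilarityConfig:
    min_fraction: float = 0.05
    min_cells: int = 20
    jaccard_source: str = "accessible"  # "accessible" | "markers"


@dataclass
class TracingConfig:
    module_fdr: float = 0.05
    fallback_top_peaks: int = 500
    holdout_fraction: float = 0.5
    gate_percentile: float = 75.0


@dataclass
class PipelineConfig:
    seed: int = 0
    qc: QCConfig = field(default_factory=QCConfig)
    tiles: TileConfig = field(default_factory=TileConfig)
    lsi: LSIConfig = field(default_factory=LSIConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    markers_genes: MarkerConfig = field(
        default_factory=lambda: MarkerConfig(fdr=0.01, log2fc=1.25)
    )
    markers_peaks: MarkerConfig = field(
        default_factory=lambda: MarkerConfig(fdr=0.1, log2fc=0.5)
    )
    peak: PeakConfig = field(default_factory=PeakConfig)
    motif: MotifConfig = field(default_factory=MotifConfig)
    genescore: GeneScoreConfig = field(default_factory=GeneScoreConfig)
    annotate: AnnotateConfig = field(default_factory=AnnotateConfig)
    metacells: MetacellConfig = field(default_factory=MetacellConfig)
    similarity: SimilarityConfig = field(default_factory=SimilarityConfig)
    tracing: TracingConfig = field(default_factory=TracingConfig)

    def validate(self) -> None:
        self.lsi.validate()
        for name, val in (
            ("qc.min_fragments", self.qc.min_fragments),
            ("qc.min_tss_enrichment", self.qc.min_tss_enrichment),
            ("tiles.size_bp", self.tiles.size_bp),
            ("lsi.n_dims", self.lsi.n_dims),
            ("cluster.k_param", self.cluster.k_param),
            ("cluster.max_clusters", self.cluster.max_clusters),
            ("peak.ceiling", self.peak.ceiling),
            ("metacells.n", self.metacells.n),
            ("markers_genes.fdr", self.markers_genes.fdr),
            ("markers_peaks.fdr", self.markers_peaks.fdr),
        ):
            if val <= 0:
                raise ValueError(f"{name} must be positive, got {val}")


def _update_dataclass(obj: Any, data: dict[str, Any], path: str) -> None:
    names = {f.name: f for f in dataclasses.fields(obj)}
    for key, value in data.items():
        if key not in names:
            raise KeyError(f"unknown configuration key: {path}{key}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current) and not isinstance(current, type):
            if not isinstance(value, dict):
                raise TypeError(f"{path}{key} must be a table")
            _update_dataclass(current, value, f"{path}{key}.")
        else:
            if isinstance(current, tuple) and isinstance(value, list):
                value = tuple(value)
            setattr(obj, key, value)


def load_config(path: str | Path) -> tuple[PipelineConfig, dict[str, Any]]:
    """Load a TOML config file.

    Returns the ``PipelineConfig`` plus the raw extras (``[sim]`` and
    ``[pipeline]`` tables) the runner consumes.  Unknown keys anywhere are
    errors, so a typo in a threshold name cannot silently fall back to a
    default.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    extras = {}
    for section in ("sim", "pipeline"):
        if section in raw:
            extras[section] = raw.pop(section)
    cfg = PipelineConfig()
    _update_dataclass(cfg, raw, "")
    cfg.validate()
    return cfg, extras
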