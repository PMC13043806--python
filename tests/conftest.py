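"""Shared fixtures: a small simulated atlas for unit tests.

The tiny atlas keeps the default generator's structure (shared stromal types
plus organ-restricted parenchyma, three peak classes, planted motifs) at a
fraction of the default scale so per-module tests stay fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from chromtrace.config import PipelineConfig
from chromtrace.simulate import SimConfig, build_truth, simulate_fragments


def tiny_sim_config(**overrides) -> SimConfig:
    base = dict(
        seed=7,
        n_tissues=3,
        cell_types_per_tissue=("endothelial", "macrophage",
                               "{tissue}_parenchyma"),
        n_cells_per_type=15,
        genome=(("chr1", 8_000_000), ("chr2", 8_000_000)),
        n_housekeeping_peaks=40,
        n_tissue_peaks_per_tissue=12,
        n_celltype_peaks_per_type=8,
        frags_per_cell_lognormal=(np.log(1800.0), 0.3),
        doublet_rate=0.04,
        lowq_cell_rate=0.05,
        motif_peaks={"Klf1": "celltype:endothelial"},
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def tiny_sim():
    config = tiny_sim_config()
    catalog = build_truth(config)
    frags, cells = simulate_fragments(catalog, config)
    return {"config": config, "catalog": catalog, "frags": frags,
            "cells": cells}


@pytest.fixture(scope="session")
def pipeline_config() -> PipelineConfig:
    return PipelineConfig(seed=7)
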