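"""Shared driver plumbing: one cached pipeline context for all analysis steps.

Each numbered script extends the cached context with the stages it needs, so
re-running the sequence 01..07 computes every stage exactly once.  The cache
lives under scratch/ (bulky, disposable); tables land under results/.
"""

from __future__ import annotations

import pickle
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
CACHE = ROOT / "scratch" / "analysis_ctx.pkl"
SEED = 1

sys.path.insert(0, str(ROOT / "src"))

from chromtrace.config import PipelineConfig  # noqa: E402
from chromtrace.pipeline import STAGES, _STAGE_FN  # noqa: E402
from chromtrace.simulate import SimConfig  # noqa: E402


def get_context(through_stage: str) -> dict:
    """Load the cached context and run any missing stages up to the target."""
    if CACHE.exists():
        with open(CACHE, "rb") as fh:
            ctx = pickle.load(fh)
    else:
        ctx = {"sim_config": SimConfig(seed=SEED),
               "config": PipelineConfig(seed=SEED), "done": []}
    want = STAGES[: STAGES.index(through_stage) + 1]
    changed = False
    for stage in want:
        if stage in ctx["done"]:
            continue
        _STAGE_FN[stage](ctx)
        ctx["done"].append(stage)
        changed = True
    if changed:
        CACHE.parent.mkdir(parents=True, exist_ok=True)
        with open(CACHE, "wb") as fh:
            pickle.dump(ctx, fh)
    RESULTS.mkdir(exist_ok=True)
    return ctx
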