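"""Tissue-of-origin tracing of held-out stromal cells.

Per stromal type, metacell Jaccard modules are associated to tissues
(hypergeometric + BH), module accessible sets yield tissue-unique peak
signatures from training cells only, and held-out stromal cells are assigned
to the tissue whose signature their binarized peak profile best matches.
"""

import pandas as pd

from common import RESULTS, get_context

ctx = get_context("trace")
preds = ctx["origin_predictions"]
preds.to_csv(RESULTS / "07_origin_predictions.tsv", sep="\t", index=False,
              float_format="%.4g")
conf = pd.crosstab(preds["true_tissue"], preds["predicted_tissue"])
conf.to_csv(RESULTS / "07_confusion.tsv", sep="\t")

print(f"held-out stromal cells: {len(preds)}; "
      f"called: {preds['predicted_tissue'].notna().mean():.1%}")
print(f"tissue-of-origin accuracy (among called): "
      f"{ctx['origin_accuracy']:.3f}")
by_type = preds.assign(ok=preds["predicted_tissue"] == preds["true_tissue"]) \
    .groupby("cell_type")["ok"].mean()
print("per-type accuracy:")
print(by_type.round(3).to_string())
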