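"""Capped peak matrix, gene activity scores, and marker detection.

Wilcoxon group-vs-rest tests per cell type: gene-score markers at
FDR <= 0.01 & log2FC >= 1.25, peak markers at FDR <= 0.1 & log2FC >= 0.5.
Marker-peak recall/precision are evaluated against the truth-derived
expected-marker oracle.
"""

import pandas as pd

from common import RESULTS, get_context
from chromtrace.simulate import expected_marker_peaks

ctx = get_context("markers")
mk = ctx["markers_peaks"]
mk[mk["passes"]].to_csv(RESULTS / "04_markers_peaks_passing.tsv", sep="\t",
                        index=False, float_format="%.4g")
mg = ctx["markers_genes"]
mg[mg["passes"]].to_csv(RESULTS / "04_markers_genes_passing.tsv", sep="\t",
                        index=False, float_format="%.4g")

exp = expected_marker_peaks(ctx["catalog"], ctx["sim_config"],
                            ctx["config"].markers_peaks.log2fc)
label_to_id = dict(zip(ctx["peak_matrix"].features,
                       ctx["peakset"].table["peak_id"]))
rows = []
for ct, truth in sorted(exp.items()):
    pred = {label_to_id[f]
            for f in mk[(mk["group"] == ct) & mk["passes"]]["feature"]}
    tp = len(pred & truth)
    rows.append((ct, len(truth), len(pred), tp / max(len(truth), 1),
                 tp / max(len(pred), 1)))
recov = pd.DataFrame(rows, columns=["cell_type", "n_expected", "n_called",
                                    "recall", "precision"])
recov.to_csv(RESULTS / "04_marker_recovery.tsv", sep="\t", index=False)
print(recov.to_string(index=False))
print(f"mean recall {recov['recall'].mean():.3f}, "
      f"mean precision {recov['precision'].mean():.3f}")
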