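"""Per-barcode QC: fragment depth and TSS enrichment, with the 1000/4 filter.

Planted low-quality barcodes (background-only, shallow) should fail both
thresholds; normal cells should pass.
"""

from common import RESULTS, get_context

ctx = get_context("qc")
metrics = ctx["qc_metrics"].merge(
    ctx["cells"][["barcode", "is_lowq", "is_doublet"]], on="barcode")
summary = metrics.groupby(["is_lowq", "is_doublet"]).agg(
    n=("barcode", "size"), n_pass=("pass_filter", "sum"),
    median_fragments=("n_fragments", "median"),
    median_tss_enrichment=("tss_enrichment", "median"))
summary.to_csv(RESULTS / "02_qc_summary.tsv", sep="\t")

lowq = metrics[metrics["is_lowq"]]
normal = metrics[~metrics["is_lowq"] & ~metrics["is_doublet"]]
print(f"retained {metrics['pass_filter'].sum()} / {len(metrics)} barcodes "
      f"(>=1000 fragments and TSS enrichment >= 4)")
print(f"low-quality excluded: {(~lowq['pass_filter']).mean():.1%}; "
      f"normal retained: {normal['pass_filter'].mean():.1%}")
print(f"median TSS enrichment: normal {normal['tss_enrichment'].median():.1f}"
      f" vs low-quality {lowq['tss_enrichment'].median():.2f}")
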