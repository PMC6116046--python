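"""Link W degeneration to GC erosion and female expression decline.

Merges the divergence, GC and expression tables for the selected genes and
runs the two correlation analyses: Z/W GC ratio vs divergence, and
log2(F/M) expression vs dN, dS and dN/dS. Writes the merged per-gene table
and a JSON summary of every statistic.
"""

import json
from pathlib import Path

import pandas as pd

from neosex.report import expression_divergence_analysis, gc_divergence_analysis

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"


def main() -> None:
    selected = pd.read_csv(OUT / "selected_transcripts.tsv", sep="\t")
    gc = pd.read_csv(OUT / "gc_stats.tsv", sep="\t")
    de = pd.read_csv(OUT / "sex_bias_de.tsv", sep="\t", index_col=0)

    merged = selected.merge(gc, on="gene_id", how="left").merge(
        de[["log2fc_FM", "padj", "significant"]],
        left_on="gene_id",
        right_index=True,
        how="left",
    )
    merged.to_csv(OUT / "report_genes.tsv", sep="\t", index=False,
                  float_format="%.8g")

    summary = {
        "n_genes": int(len(merged)),
        "gc_analyses": gc_divergence_analysis(merged),
        "expression_analyses": expression_divergence_analysis(merged),
    }
    (OUT / "correlations.json").write_text(json.dumps(summary, indent=2,
                                                      sort_keys=True) + "\n")

    gc_t = summary["gc_analyses"]
    ex_t = summary["expression_analyses"]
    print(f"merged report: {summary['n_genes']} genes")
    print(f"GC ratio vs dS: r_s={gc_t['gc_ratio_vs_ds']['r_s']:.2f} "
          f"(p={gc_t['gc_ratio_vs_ds']['p']:.2g}); vs dN: "
          f"r_s={gc_t['gc_ratio_vs_dn']['r_s']:.2f} "
          f"(p={gc_t['gc_ratio_vs_dn']['p']:.2g})")
    for metric in ("dn", "ds", "omega"):
        r = ex_t[f"log2fc_vs_{metric}"]
        if r.get("r_s") is not None:
            print(f"log2(F/M) vs {metric}: r_s={r['r_s']:.2f} (p={r['p']:.2g}, "
                  f"n={r['n']})")


if __name__ == "__main__":
    main()
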