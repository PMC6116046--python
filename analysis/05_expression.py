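"""Test sex-biased expression on the simulated RNA-seq counts.

Median-of-ratios normalization, per-gene NB Wald test of female vs male,
BH-FDR correction; reports the number of significant genes and the mean
log2(F/M) of the analysed gene set.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from neosex.expression import test_sex_bias, write_de_table
from neosex.phasing import read_sex_map

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"


def main() -> None:
    counts = pd.read_csv(OUT / "rna_counts.tsv", sep="\t", index_col=0)
    sexes = read_sex_map(OUT / "rna_sex_map.tsv")
    de = test_sex_bias(counts, sexes)
    write_de_table(de, OUT / "sex_bias_de.tsv")

    finite = de[np.isfinite(de["log2fc_FM"])]
    n_sig = int(de["significant"].sum())
    print(f"tested {len(de)} genes: {n_sig} significant at padj < 0.05")
    print(f"mean log2(F/M) = {finite['log2fc_FM'].mean():.3f} "
          f"+/- {finite['log2fc_FM'].std(ddof=1) / np.sqrt(len(finite)):.3f} SE")

    truth = pd.read_csv(OUT / "truth_table.tsv", sep="\t").set_index("gene_id")
    lost = truth.index[truth["w_present"] == 0]
    lost_lfc = de.loc[de.index.intersection(lost), "log2fc_FM"]
    present_lfc = de.loc[de.index.difference(lost), "log2fc_FM"]
    # counts here span only the sex-linked gene set, so size factors are
    # anchored on its average female reduction: log2 ratios are relative
    # to that baseline, not to an autosomal reference
    print(f"median log2(F/M): W-deleted {lost_lfc.median():.3f} "
          f"(n={len(lost_lfc)}) vs W-present {present_lfc.median():.3f} "
          f"(n={len(present_lfc)}) -- hemizygous genes sit lowest")


if __name__ == "__main__":
    main()
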