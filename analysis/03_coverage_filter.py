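"""Flag transcripts without a W gametolog from female/male DNA coverage.

Normalizes per-exon coverage by library totals, applies the 70% rule and,
because this run is synthetic, scores the calls against the recorded
truth.
"""

from pathlib import Path

import pandas as pd

from neosex.coverage import (
    filter_w_absent,
    library_size_factors,
    transcript_coverage,
    write_coverage_report,
)
from neosex.phasing import read_sex_map

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"


def main() -> None:
    cov = pd.read_csv(OUT / "dna_coverage.tsv", sep="\t")
    totals = pd.read_csv(OUT / "dna_totals.tsv", sep="\t", index_col=0).iloc[:, 0]
    sexes = read_sex_map(OUT / "dna_sex_map.tsv")
    records = transcript_coverage(cov, library_size_factors(totals), sexes)
    write_coverage_report(records, OUT / "coverage_report.tsv")
    retained, removed = filter_w_absent(records)
    print(f"coverage filter: retained {len(retained)}, removed {len(removed)} "
          f"transcripts (female < 70% of male coverage)")

    truth = pd.read_csv(OUT / "truth_table.tsv", sep="\t")
    merged = records.merge(truth, on="transcript_id")
    tp = ((merged["w_absent"]) & (merged["w_present"] == 0)).sum()
    fp = ((merged["w_absent"]) & (merged["w_present"] == 1)).sum()
    fn = ((~merged["w_absent"]) & (merged["w_present"] == 0)).sum()
    tn = ((~merged["w_absent"]) & (merged["w_present"] == 1)).sum()
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    print(f"vs truth: sensitivity {sens:.3f}, specificity {spec:.3f}")


if __name__ == "__main__":
    main()
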