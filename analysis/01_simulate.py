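"""Generate the synthetic gametolog system every later stage analyses.

Simulates 200 neo-sex-linked genes under the default study conditions
(Z-W synonymous divergence ~0.05, relaxed selection on W, 10% W loss,
GC-biased substitution on Z) and writes truth files, the sex-labelled VCF
with BED exons, per-exon DNA coverage and the RNA-seq count matrix to
results/analysis/.
"""

from pathlib import Path

from neosex import SimulationConfig, simulate_gene_set
from neosex.simulate import (
    emit_dna_coverage,
    emit_expression_counts,
    emit_vcf,
    write_sex_map,
    write_truth,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"
CONFIG = SimulationConfig(n_genes=200, codons_per_gene=500, seed=42)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genes = simulate_gene_set(CONFIG)
    write_truth(genes, CONFIG, OUT)
    n_records = emit_vcf(genes, CONFIG, OUT / "variants.vcf", OUT / "exons.bed")
    write_sex_map(CONFIG.dna_samples(), OUT / "dna_sex_map.tsv")
    cov, totals = emit_dna_coverage(genes, CONFIG)
    cov.to_csv(OUT / "dna_coverage.tsv", sep="\t", index=False)
    totals.rename_axis("sample").to_csv(OUT / "dna_totals.tsv", sep="\t")
    counts, rna_sexes = emit_expression_counts(genes, CONFIG)
    counts.to_csv(OUT / "rna_counts.tsv", sep="\t")
    write_sex_map(list(rna_sexes.items()), OUT / "rna_sex_map.tsv")

    n_lost = sum(1 for g in genes if not g.w_present)
    print(f"simulated {len(genes)} genes ({n_lost} with W deleted), "
          f"{n_records} VCF records -> {OUT}")


if __name__ == "__main__":
    main()
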