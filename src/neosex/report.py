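"""Integration of divergence, GC and expression tables into the final report.

Drives the full pipeline on a synthetic gametolog system: simulate ->
emit VCF/BED/coverage/expression -> phase -> coverage-filter -> divergence
-> differential expression -> correlation analyses. Each stage writes its
artifact to disk and the run ends in a machine-readable JSON summary that
is byte-identical across reruns with the same seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coverage as cov
from . import divergence as dv
from . import expression as ex
from . import phasing as ph
from . import simulate as sim
from .stats import CorrelationResult, TestResult, signed_rank, spearman

SCHEMA_VERSION = 1


@dataclass
class ReportBundle:
    """Merged per-gene table plus every test the report runs."""

    genes: pd.DataFrame                 # one row per retained gene
    outgroup_tests: dict = field(default_factory=dict)
    gc_tests: dict = field(default_factory=dict)
    expression_tests: dict = field(default_factory=dict)
    filter_counts: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "config": self.config,
            "n_genes_reported": int(len(self.genes)),
            "filters": self.filter_counts,
            "outgroup_contrast": self.outgroup_tests,
            "gc_analyses": self.gc_tests,
            "expression_analyses": self.expression_tests,
        }


def _corr_dict(c: CorrelationResult) -> dict:
    return {"r_s": c.r_s, "n": c.n, "p": c.p, "method": c.method}


def _test_dict(t: TestResult) -> dict:
    return {"statistic": t.statistic, "p": t.p, "n": t.n, "note": t.note}


def gc_divergence_analysis(table: pd.DataFrame) -> dict:
    """GC erosion analyses on a merged per-gene table.

    Expects columns gc_Z, gc_W, gc_ratio_ZW, dn, ds. Runs the paired
    Z-vs-W GC contrast (signed-rank) and Spearman correlations of the Z/W
    GC ratio against dN and dS: under GC-biased substitution on the
    recombining Z only, the ratio should grow with divergence.
    """
    t = table.dropna(subset=["gc_Z", "gc_W", "gc_ratio_ZW", "dn", "ds"])
    out: dict = {"n": int(len(t))}
    if len(t) >= 2:
        out["gc_z_vs_w_signed_rank"] = _test_dict(signed_rank(t["gc_Z"], t["gc_W"]))
        out["median_gc_Z"] = float(t["gc_Z"].median())
        out["median_gc_W"] = float(t["gc_W"].median())
    if len(t) >= 3:
        out["gc_ratio_vs_dn"] = _corr_dict(
            spearman(t["gc_ratio_ZW"], t["dn"], "gc_ratio_ZW~dn")
        )
        out["gc_ratio_vs_ds"] = _corr_dict(
            spearman(t["gc_ratio_ZW"], t["ds"], "gc_ratio_ZW~ds")
        )
    return out


def expression_divergence_analysis(table: pd.DataFrame) -> dict:
    """Spearman correlations of log2(F/M) expression against dN, dS, dN/dS.

    A negative correlation with dN is the signature of W degeneration
    driving female expression loss (incomplete dosage compensation).
    """
    out: dict = {}
    for metric in ("dn", "ds", "omega"):
        t = table.dropna(subset=["log2fc_FM", metric])
        t = t[np.isfinite(t["log2fc_FM"]) & np.isfinite(t[metric])]
        if len(t) >= 3:
            out[f"log2fc_vs_{metric}"] = _corr_dict(
                spearman(t["log2fc_FM"], t[metric], f"log2fc_FM~{metric}")
            )
        else:
            out[f"log2fc_vs_{metric}"] = {"n": int(len(t)), "r_s": None, "p": None}
    out["n_merged"] = int(len(table))
    return out


def run_pipeline(config: sim.SimulationConfig, outdir: str | Path) -> ReportBundle:
    """Simulate one gametolog system and run every analysis stage on it."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # -- stage 1: simulate ---------------------------------------------
    genes = sim.simulate_gene_set(config)
    sim.write_truth(genes, config, outdir)
    vcf_path = outdir / "variants.vcf"
    bed_path = outdir / "exons.bed"
    sim.emit_vcf(genes, config, vcf_path, bed_path)
    sim.write_sex_map(config.dna_samples(), outdir / "dna_sex_map.tsv")
    cov_df, totals = sim.emit_dna_coverage(genes, config)
    cov_df.to_csv(outdir / "dna_coverage.tsv", sep="\t", index=False)
    totals.rename_axis("sample").to_csv(outdir / "dna_totals.tsv", sep="\t")
    counts, rna_sexes = sim.emit_expression_counts(genes, config)
    counts.to_csv(outdir / "rna_counts.tsv", sep="\t")
    sim.write_sex_map(list(rna_sexes.items()), outdir / "rna_sex_map.tsv")

    # -- stage 2: phase -------------------------------------------------
    sex_map = {s: sx for s, sx in config.dna_samples()}
    phased = ph.phase_vcf(vcf_path, bed_path, sex_map)
    ph.write_phased_fasta(phased, outdir / "phased.fasta")
    ph.write_audit_table(phased, outdir / "phasing_audit.tsv")

    # -- stage 3: coverage filter ---------------------------------------
    factors = cov.library_size_factors(totals)
    cov_records = cov.transcript_coverage(cov_df, factors, sex_map)
    cov.write_coverage_report(cov_records, outdir / "coverage_report.tsv")
    retained_ids, removed_ids = cov.filter_w_absent(cov_records)
    retained = set(retained_ids)

    # -- stage 4: divergence --------------------------------------------
    by_tid = {g.transcript_id: g for g in genes}
    div_rows: list[dv.DivergenceEstimate] = []
    gc_rows: list[dv.GCStat] = []
    sat_or_empty = 0
    for tid in sorted(retained):
        gene = by_tid[tid]
        p = phased[tid]
        aln = dv.mask_codons(
            {"Z": p.z_seq, "W": p.w_seq, "outgroup": gene.seq_outgroup},
            gene_id=gene.gene_id,
        )
        if aln.n_codons_retained == 0:
            sat_or_empty += 1
            continue
        est_zw = dv.pairwise_dnds(aln.seqs["Z"], aln.seqs["W"], gene.gene_id, "Z-W")
        est_zo = dv.pairwise_dnds(
            aln.seqs["Z"], aln.seqs["outgroup"], gene.gene_id, "Z-outgroup"
        )
        est_wo = dv.pairwise_dnds(
            aln.seqs["W"], aln.seqs["outgroup"], gene.gene_id, "W-outgroup"
        )
        if est_zw.saturated:
            sat_or_empty += 1
            continue
        div_rows += [est_zw, est_zo, est_wo]
        gc_rows.append(dv.gc_stats(aln))

    est_table = dv.estimates_table(div_rows) if div_rows else pd.DataFrame(
        columns=["gene_id", "pair", "s_sites", "n_sites", "sd", "nd",
                 "ps", "pn", "ds", "dn", "omega", "saturated"]
    )
    est_table.to_csv(outdir / "divergence.tsv", sep="\t", index=False,
                     float_format="%.8g")

    zw = est_table[est_table["pair"] == "Z-W"].copy()
    tid_of = {g.gene_id: g.transcript_id for g in genes}
    zw["transcript_id"] = zw["gene_id"].map(tid_of)
    zw["retained_bp"] = zw["s_sites"] + zw["n_sites"]
    selected, sel_counts = (
        dv.select_transcripts(zw) if len(zw) else (zw, {"input": 0, "retained": 0})
    )
    selected_genes = set(selected["gene_id"]) if len(selected) else set()

    outgroup_paired, outgroup_tests = (
        dv.outgroup_contrast(est_table[est_table["gene_id"].isin(selected_genes)])
        if selected_genes
        else (pd.DataFrame(), {"n_genes": 0})
    )
    if len(outgroup_paired):
        outgroup_paired.to_csv(outdir / "outgroup_contrast.tsv", sep="\t",
                               index=False, float_format="%.8g")

    # -- stage 5: expression --------------------------------------------
    de = ex.test_sex_bias(counts, rna_sexes)
    ex.write_de_table(de, outdir / "sex_bias_de.tsv")

    # -- stage 6: merge + correlations ----------------------------------
    gc_table = pd.DataFrame([vars(g) for g in gc_rows]) if gc_rows else pd.DataFrame(
        columns=["gene_id", "gc_Z", "gc_W", "gc_outgroup", "gc_ratio_ZW"]
    )
    merged = selected.merge(gc_table, on="gene_id", how="left") if len(selected) else (
        pd.DataFrame(columns=list(zw.columns) + ["gc_Z", "gc_W", "gc_ratio_ZW"])
    )
    merged = merged.merge(
        de[["log2fc_FM", "p", "padj", "significant"]],
        left_on="gene_id",
        right_index=True,
        how="left",
    )
    truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "w_present": [g.w_present for g in genes],
            "true_dN_ZW": [g.true_dN_ZW for g in genes],
            "true_dS_ZW": [g.true_dS_ZW for g in genes],
        }
    )
    merged = merged.merge(truth, on="gene_id", how="left")
    merged.to_csv(outdir / "report_genes.tsv", sep="\t", index=False,
                  float_format="%.8g")

    gc_tests = gc_divergence_analysis(merged) if len(merged) else {"n": 0}
    expr_tests = expression_divergence_analysis(merged) if len(merged) else {}

    bundle = ReportBundle(
        genes=merged,
        outgroup_tests=outgroup_tests,
        gc_tests=gc_tests,
        expression_tests=expr_tests,
        filter_counts={
            "simulated": len(genes),
            "coverage_retained": len(retained_ids),
            "coverage_removed": len(removed_ids),
            "saturated_or_empty": sat_or_empty,
            **{f"selection_{k}": v for k, v in sel_counts.items()},
        },
        config=dataclasses.asdict(config),
    )
    (outdir / "summary.json").write_text(
        json.dumps(bundle.summary(), indent=2, sort_keys=True, allow_nan=True) + "\n"
    )
    return bundle
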