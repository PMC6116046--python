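"""Ground-truth properties of the gametolog-evolution generator."""

import numpy as np
import pytest

from neosex import SimulationConfig, simulate_gene_set
from neosex.codon import CODON_TO_AA, is_stop
from neosex.divergence import mask_codons, pairwise_dnds
from neosex.simulate import (
    emit_dna_coverage,
    emit_expression_counts,
    emit_vcf,
    exon_intervals,
)


def test_config_validation_rejects_bad_parameters():
    with pytest.raises(ValueError):
        SimulationConfig(t_sexlinked=0.05, t_outgroup=0.04).validate()
    with pytest.raises(ValueError):
        SimulationConfig(t_outgroup=0.9).validate()  # saturation guard
    with pytest.raises(ValueError):
        SimulationConfig(w_loss_fraction=1.5).validate()
    with pytest.raises(ValueError):
        SimulationConfig(omega_W=0.0).validate()


def test_zero_sexlinked_branch_means_identical_gametologs():
    cfg = SimulationConfig(
        n_genes=6, codons_per_gene=100, t_sexlinked=0.0, w_loss_fraction=0.0, seed=5
    )
    for g in simulate_gene_set(cfg):
        assert g.seq_Z == g.seq_W
        assert g.true_dS_ZW == 0.0
        assert g.true_dN_ZW == 0.0


def test_sequences_are_valid_open_reading_frames(default_genes):
    _, genes = default_genes
    for g in genes[:20]:
        for seq in (g.seq_outgroup, g.seq_Z, g.seq_W):
            if seq is None:
                continue
            assert len(seq) % 3 == 0
            codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
            assert not any(is_stop(c) for c in codons)
            assert all(c in CODON_TO_AA for c in codons)


def test_same_seed_reproduces_byte_identical_outputs(tmp_path):
    cfg = SimulationConfig(n_genes=4, codons_per_gene=60, seed=9)
    for run in ("a", "b"):
        genes = simulate_gene_set(cfg)
        emit_vcf(genes, cfg, tmp_path / f"{run}.vcf", tmp_path / f"{run}.bed")
        cov, totals = emit_dna_coverage(genes, cfg)
        cov.to_csv(tmp_path / f"{run}.cov.tsv", sep="\t", index=False)
        counts, _ = emit_expression_counts(genes, cfg)
        counts.to_csv(tmp_path / f"{run}.rna.tsv", sep="\t")
    for ext in ("vcf", "bed", "cov.tsv", "rna.tsv"):
        assert (tmp_path / f"a.{ext}").read_bytes() == (
            tmp_path / f"b.{ext}"
        ).read_bytes()


def test_omega_recovery_from_truth_pairs():
    """The counting estimator on truth Z/W pairs recovers the mean of the
    two lineage omegas (homogeneous rates, enough divergence to count)."""
    cfg = SimulationConfig(
        n_genes=200,
        codons_per_gene=500,
        t_sexlinked=0.1,
        t_outgroup=0.15,
        omega_Z=0.1,
        omega_W=0.5,
        rate_sd_log=0.0,
        gc_bias_Z=1.0,
        w_loss_fraction=0.0,
        seed=17,
    )
    genes = simulate_gene_set(cfg)
    omegas, true_dn, true_ds, est_dn, est_ds = [], [], [], [], []
    for g in genes:
        est = pairwise_dnds(g.seq_Z, g.seq_W, g.gene_id, "Z-W")
        if est.saturated or not np.isfinite(est.omega):
            continue
        omegas.append(est.omega)
        true_dn.append(g.true_dN_ZW)
        true_ds.append(g.true_dS_ZW)
        est_dn.append(est.dn)
        est_ds.append(est.ds)
    target = (cfg.omega_Z + cfg.omega_W) / 2
    assert np.mean(omegas) == pytest.approx(target, abs=0.1)
    # estimates track the recorded substitution events gene by gene
    # (homogeneous rates: spread is pure Poisson, so correlation is capped
    # by estimation noise)
    assert np.corrcoef(true_dn, est_dn)[0, 1] > 0.85
    assert np.corrcoef(true_ds, est_ds)[0, 1] > 0.85


def test_estimated_ds_tracks_truth_under_default_heterogeneity():
    from scipy.stats import spearmanr

    cfg = SimulationConfig(n_genes=200, codons_per_gene=300, w_loss_fraction=0.0,
                           seed=19)
    genes = simulate_gene_set(cfg)
    true_ds, est_ds = [], []
    for g in genes:
        est = pairwise_dnds(g.seq_Z, g.seq_W)
        if est.saturated:
            continue
        true_ds.append(g.true_dS_ZW)
        est_ds.append(est.ds)
    assert spearmanr(true_ds, est_ds).statistic >= 0.9


def test_vcf_genotype_patterns_follow_the_zw_model(tmp_path, clean_config):
    from neosex.simulate import CONTIG

    genes = simulate_gene_set(clean_config)
    vcf_path = tmp_path / "v.vcf"
    n = emit_vcf(genes, clean_config, vcf_path)
    lines = [
        l.split("\t")
        for l in vcf_path.read_text().splitlines()
        if not l.startswith("#")
    ]
    # corruption 0: one record per reference base
    assert n == len(lines) == clean_config.gene_length * len(genes)

    lost = {i for i, g in enumerate(genes) if not g.w_present}
    length = clean_config.gene_length
    checked_het = checked_hemi = 0
    for rec in lines:
        pos0 = int(rec[1]) - 1
        gene_idx, offset = divmod(pos0, length)
        g = genes[gene_idx]
        ref, alt = rec[3], rec[4]
        gts = [f.split(":")[0] for f in rec[9:]]
        z = g.seq_Z[offset]
        w = (g.seq_W or g.seq_Z)[offset]
        assert rec[0] == CONTIG
        assert ref == g.seq_outgroup[offset]
        # males are Z/Z; a Z=ref, W=alt site must be hom-ref males + het females
        if z == ref and w != ref and g.w_present:
            assert gts[:2] == ["0/0", "0/0"]
            assert sorted(gts[2].split("/")) == ["0", "1"]
            checked_het += 1
        if gene_idx in lost:
            assert gts[2] == gts[3] and gts[2].split("/")[0] == gts[2].split("/")[1]
            checked_hemi += 1
    assert checked_het > 0 and checked_hemi > 0


def test_exon_intervals_tile_each_gene():
    cfg = SimulationConfig(n_genes=3, codons_per_gene=67)
    for g in range(3):
        ivals = exon_intervals(g, cfg)
        assert len(ivals) == 3
        assert ivals[0][0] == g * cfg.gene_length
        assert ivals[-1][1] == (g + 1) * cfg.gene_length
        assert all(a[1] == b[0] for a, b in zip(ivals, ivals[1:]))


def test_coverage_expectations_track_w_loss():
    cfg = SimulationConfig(
        n_genes=120, codons_per_gene=200, w_loss_fraction=0.3, seed=23
    )
    genes = simulate_gene_set(cfg)
    cov, totals = emit_dna_coverage(genes, cfg)
    cov["depth"] = cov["count"] / cov["exon_length"]
    per = cov.groupby(["transcript_id", "sample"])["depth"].mean().unstack()
    females = [s for s, sex in cfg.dna_samples() if sex == "F"]
    males = [s for s, sex in cfg.dna_samples() if sex == "M"]
    # normalize away library multipliers using the emitted totals
    norm = per / (totals / totals.max())
    ratio = norm[females].mean(axis=1) / norm[males].mean(axis=1)
    present = {g.transcript_id: g.w_present for g in genes}
    r_present = ratio[[t for t in ratio.index if present[t]]]
    r_lost = ratio[[t for t in ratio.index if not present[t]]]
    assert r_present.mean() == pytest.approx(1.0, abs=0.05)
    assert r_lost.mean() == pytest.approx(0.5, abs=0.05)


def test_expression_link_endpoints_and_monotonicity():
    from scipy.stats import spearmanr

    cfg = SimulationConfig(n_genes=150, codons_per_gene=120, beta_link=0.0,
                           w_loss_fraction=0.0, seed=31)
    genes = simulate_gene_set(cfg)
    assert all(g.female_expr_ratio == 1.0 for g in genes)

    cfg2 = SimulationConfig(n_genes=150, codons_per_gene=120, beta_link=1.0,
                            w_loss_fraction=0.0, seed=31)
    genes2 = simulate_gene_set(cfg2)
    for g in genes2:
        if g.true_dN_ZW >= cfg2.d_cap:
            assert g.female_expr_ratio == pytest.approx(0.5)
    rho = spearmanr(
        [g.female_expr_ratio for g in genes2], [g.true_dN_ZW for g in genes2]
    ).statistic
    assert rho <= 0

    cfg3 = SimulationConfig(n_genes=10, codons_per_gene=120, w_loss_fraction=1.0,
                            seed=31)
    genes3 = simulate_gene_set(cfg3)
    assert all(g.female_expr_ratio == 0.5 for g in genes3)
    assert all(g.seq_W is None for g in genes3)


def test_expression_counts_scale_with_ratio_and_libsize():
    cfg = SimulationConfig(n_genes=400, codons_per_gene=30, w_loss_fraction=1.0,
                           expr_dispersion=0.02, seed=41)
    genes = simulate_gene_set(cfg)
    counts, sexes = emit_expression_counts(genes, cfg)
    males = [s for s, x in sexes.items() if x == "M"]
    females = [s for s, x in sexes.items() if x == "F"]
    # per-sample means vary with library jitter, but the pooled F/M ratio
    # across many genes must sit near the truth 0.5 after scaling out
    # library sizes (library jitter is sex-balanced only in expectation,
    # so compare pooled gene means sample-wise)
    gene_ratio = counts[females].mean(axis=1).sum() / counts[males].mean(axis=1).sum()
    assert 0.3 < gene_ratio < 0.75


def test_dS_exchangeable_between_z_and_w_without_gc_bias():
    """With equal omegas and no GC bias the Z and W branches are
    statistically exchangeable: paired dN difference centred at zero."""
    from scipy import stats

    cfg = SimulationConfig(
        n_genes=200, codons_per_gene=200, omega_Z=0.3, omega_W=0.3,
        gc_bias_Z=1.0, w_loss_fraction=0.0, rate_sd_log=0.0, seed=57,
    )
    genes = simulate_gene_set(cfg)
    dn_z, dn_w = [], []
    for g in genes:
        ez = pairwise_dnds(g.seq_Z, g.seq_outgroup)
        ew = pairwise_dnds(g.seq_W, g.seq_outgroup)
        if ez.saturated or ew.saturated:
            continue
        dn_z.append(ez.dn)
        dn_w.append(ew.dn)
    t, p = stats.ttest_rel(dn_w, dn_z)
    assert p > 0.01
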