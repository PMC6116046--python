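"""Synthetic gametolog-evolution generator.

Emulates the data a neo-sex-chromosome resequencing study produces: a pair
of sex chromosomes (Z, W) that stopped recombining after the focal lineage
split from an outgroup, genotyped in ZZ males and ZW females against the
outgroup reference. The generator produces, with known ground truth:

* coding sequences for outgroup, Z and W under a codon substitution model
  with transition bias (kappa), lineage-specific selection (omega thinning
  of non-synonymous proposals) and optional GC-biased substitution on the
  Z lineage;
* a VCF v4.2 of per-base diploid genotypes (monomorphic records included)
  with BED exon annotations, optionally corrupted to exercise masking;
* per-exon DNA read counts with hemizygous (W-deleted) genes at half the
  female coverage;
* an RNA-seq count matrix in which female expression declines with the
  gene's realized non-synonymous Z-W divergence (the degeneration-
  expression link), and sits at exactly 50% of male expression for
  W-deleted genes under no compensation.

Branch lengths are expressed as expected substitution *proposals* per site,
i.e. the neutral divergence scale: synonymous divergence per synonymous
site realizes the branch length, non-synonymous divergence realizes
omega times it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .codon import BASES, SENSE_CODONS, CODON_TO_AA, is_stop, is_transition, ng86_sites

CONTIG = "neo4A"
_AT = frozenset("AT")
_GC = frozenset("GC")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic gametolog system.

    Defaults are calibrated to the neo-sex chromosome system the package
    models: Z-W synonymous divergence around 0.05, outgroup split slightly
    older than recombination arrest (22 vs 19 My), strong purifying
    selection on Z (omega 0.1) and relaxed selection on W (omega 0.5).
    """

    n_genes: int = 200
    codons_per_gene: int = 500
    t_outgroup: float = 0.029      # proposals/site, split with outgroup
    t_sexlinked: float = 0.025     # proposals/site since Z-W recombination stopped
    omega_Z: float = 0.1
    omega_W: float = 0.5
    kappa: float = 2.0
    gc_bias_Z: float = 2.0         # weight on A/T->G/C proposals, Z lineage only
    w_loss_fraction: float = 0.1
    rate_sd_log: float = 1.0       # sd of per-gene lognormal rate multiplier
    n_males_dna: int = 2
    n_females_dna: int = 2
    n_males_rna: int = 6
    n_females_rna: int = 6
    mean_depth: float = 30.0       # expected per-base DNA coverage
    read_length: int = 150
    expr_mean: float = 500.0
    expr_dispersion: float = 0.05  # NB variance = mu + disp * mu^2
    beta_link: float = 1.0         # coupling of female expression to W divergence
    d_cap: float = 0.02            # dN at which the link saturates (full silencing)
    # per-record corruption probabilities (independent); defaults sum to 5%
    p_low_qual: float = 0.0125
    p_low_dp: float = 0.0125
    p_missing_gt: float = 0.0125
    p_triallelic: float = 0.0125
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.codons_per_gene < 2:
            raise ValueError("need >=1 gene and >=2 codons per gene")
        if not (0 <= self.t_sexlinked < self.t_outgroup):
            raise ValueError("require 0 <= t_sexlinked < t_outgroup")
        if 2 * self.t_outgroup > 1.5:
            raise ValueError(
                "expected pairwise divergence exceeds the saturation guard "
                f"(2*t_outgroup = {2 * self.t_outgroup:.3f} > 1.5)"
            )
        for name in ("omega_Z", "omega_W", "kappa", "gc_bias_Z"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.w_loss_fraction <= 1.0:
            raise ValueError("w_loss_fraction must be in [0, 1]")
        if not 0.0 <= self.beta_link <= 1.0:
            raise ValueError("beta_link must be in [0, 1]")
        for name in ("p_low_qual", "p_low_dp", "p_missing_gt", "p_triallelic"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if min(self.n_males_dna, self.n_females_dna) < 1:
            raise ValueError("need >=1 DNA sample per sex")
        if self.d_cap <= 0:
            raise ValueError("d_cap must be > 0")
        if self.rate_sd_log < 0:
            raise ValueError("rate_sd_log must be >= 0")

    def with_corruption(self, total: float) -> "SimulationConfig":
        """Copy with the four corruption probabilities set to total/4 each."""
        p = total / 4.0
        return dataclasses.replace(
            self, p_low_qual=p, p_low_dp=p, p_missing_gt=p, p_triallelic=p
        )

    @property
    def gene_length(self) -> int:
        return 3 * self.codons_per_gene

    def dna_samples(self) -> list[tuple[str, str]]:
        return [(f"M{i+1}", "M") for i in range(self.n_males_dna)] + [
            (f"F{i+1}", "F") for i in range(self.n_females_dna)
        ]

    def rna_samples(self) -> list[tuple[str, str]]:
        return [(f"RM{i+1}", "M") for i in range(self.n_males_rna)] + [
            (f"RF{i+1}", "F") for i in range(self.n_females_rna)
        ]


@dataclass
class GeneTruth:
    """Ground truth for one simulated gene."""

    gene_id: str
    seq_outgroup: str
    seq_Z: str
    seq_W: str | None          # None when the W copy is deleted
    w_present: bool
    true_dN_ZW: float
    true_dS_ZW: float
    female_expr_ratio: float
    rate_multiplier: float = 1.0
    n_syn_events_ZW: int = 0
    n_nonsyn_events_ZW: int = 0

    @property
    def transcript_id(self) -> str:
        return f"{self.gene_id}.t1"


def _proposal_weights(kappa: float, gc_bias: float) -> dict[str, tuple[str, np.ndarray]]:
    """Per-base target alternatives and cumulative proposal weights."""
    table = {}
    for old in BASES:
        targets = [b for b in BASES if b != old]
        w = []
        for b in targets:
            weight = kappa if is_transition(old, b) else 1.0
            if old in _AT and b in _GC:
                weight *= gc_bias
            w.append(weight)
        cum = np.cumsum(w)
        table[old] = ("".join(targets), cum / cum[-1])
    return table


def _evolve(
    seq: list[str],
    t: float,
    omega: float,
    weights: dict[str, tuple[str, np.ndarray]],
    rng: np.random.Generator,
    events: list[tuple[int, str, str, bool]] | None = None,
) -> None:
    """Evolve ``seq`` in place for branch length ``t``.

    Proposals arrive as a Poisson number of events (t per site); each picks
    a site uniformly and a target base with kappa/GC weighting. Proposals
    creating stop codons are rejected; synonymous proposals are always
    accepted; non-synonymous ones with probability omega.
    """
    length = len(seq)
    n_events = rng.poisson(t * length)
    for _ in range(n_events):
        pos = int(rng.integers(length))
        old = seq[pos]
        targets, cum = weights[old]
        new = targets[int(np.searchsorted(cum, rng.random(), side="right"))]
        cstart = 3 * (pos // 3)
        codon = seq[cstart : cstart + 3]
        mutant = "".join(
            new if cstart + k == pos else codon[k] for k in range(3)
        )
        if is_stop(mutant):
            continue
        syn = CODON_TO_AA[mutant] == CODON_TO_AA["".join(codon)]
        if syn or rng.random() < omega:
            seq[pos] = new
            if events is not None:
                events.append((pos, old, new, syn))


def _ancestral_cds(n_codons: int, rng: np.random.Generator) -> list[str]:
    codons = ["ATG"] + [
        SENSE_CODONS[int(i)]
        for i in rng.integers(len(SENSE_CODONS), size=n_codons - 1)
    ]
    return list("".join(codons))


def simulate_gene_set(config: SimulationConfig) -> list[GeneTruth]:
    """Simulate the full gene set with recorded ground truth.

    Topology: the ancestor splits into the outgroup lineage (branch
    t_outgroup) and the proto-gametolog lineage, which evolves for
    (t_outgroup - t_sexlinked) before recombination stops and Z and W
    evolve independently for t_sexlinked. The outgroup and proto branches
    evolve under omega_Z (background purifying selection); GC bias applies
    to the Z branch only. Realized Z-W divergence is computed from the
    recorded accepted substitutions against NG86 site counts of the
    proto-gametolog sequence.

    Genes differ in their substitution rate: every branch of gene g is
    scaled by a lognormal multiplier (median 1, log-sd ``rate_sd_log``,
    clipped to [0.1, 10]), reproducing the wide between-gene divergence
    spread real gametolog sets show (roughly two orders of magnitude in
    dS). Set rate_sd_log=0 for homogeneous rates.
    """
    config.validate()
    ss = np.random.SeedSequence([config.seed, 0])
    rng = np.random.default_rng(ss)
    w_neutral = _proposal_weights(config.kappa, 1.0)
    w_gc = _proposal_weights(config.kappa, config.gc_bias_Z)

    n_lost = int(round(config.w_loss_fraction * config.n_genes))
    lost = set(rng.choice(config.n_genes, size=n_lost, replace=False).tolist())

    width = max(4, len(str(config.n_genes)))
    genes: list[GeneTruth] = []
    for g in range(config.n_genes):
        anc = _ancestral_cds(config.codons_per_gene, rng)
        if config.rate_sd_log > 0:
            mult = float(np.clip(rng.lognormal(0.0, config.rate_sd_log), 0.1, 10.0))
        else:
            mult = 1.0
        out = list(anc)
        _evolve(out, mult * config.t_outgroup, config.omega_Z, w_neutral, rng)
        proto = list(anc)
        _evolve(
            proto,
            mult * (config.t_outgroup - config.t_sexlinked),
            config.omega_Z,
            w_neutral,
            rng,
        )
        s_sites = 0.0
        for c in range(config.codons_per_gene):
            s, _ = ng86_sites("".join(proto[3 * c : 3 * c + 3]))
            s_sites += s
        n_sites = 3.0 * config.codons_per_gene - s_sites

        z = list(proto)
        events_z: list = []
        _evolve(z, mult * config.t_sexlinked, config.omega_Z, w_gc, rng, events_z)
        w = list(proto)
        events_w: list = []
        _evolve(w, mult * config.t_sexlinked, config.omega_W, w_neutral, rng, events_w)

        syn_events = sum(1 for e in events_z + events_w if e[3])
        nonsyn_events = sum(1 for e in events_z + events_w if not e[3])
        true_ds = syn_events / s_sites if s_sites else 0.0
        true_dn = nonsyn_events / n_sites if n_sites else 0.0

        present = g not in lost
        if present:
            ratio = 1.0 - config.beta_link * min(true_dn / config.d_cap, 1.0) * 0.5
        else:
            ratio = 0.5
        genes.append(
            GeneTruth(
                gene_id=f"gene{g + 1:0{width}d}",
                seq_outgroup="".join(out),
                seq_Z="".join(z),
                seq_W="".join(w) if present else None,
                w_present=present,
                true_dN_ZW=true_dn,
                true_dS_ZW=true_ds,
                female_expr_ratio=ratio,
                rate_multiplier=mult,
                n_syn_events_ZW=syn_events,
                n_nonsyn_events_ZW=nonsyn_events,
            )
        )
    return genes


def exon_intervals(gene_index: int, config: SimulationConfig) -> list[tuple[int, int]]:
    """Three exons per gene: equal thirds, remainder to the last exon.

    Coordinates are 0-based half-open on the concatenated reference contig
    (gene i occupies [i*L, (i+1)*L)).
    """
    length = config.gene_length
    start = gene_index * length
    third = length // 3
    bounds = [0, third, 2 * third, length]
    return [(start + bounds[k], start + bounds[k + 1]) for k in range(3)]


def write_bed(genes: list[GeneTruth], config: SimulationConfig, path: str | Path) -> None:
    lines = []
    for g, gene in enumerate(genes):
        for k, (s, e) in enumerate(exon_intervals(g, config)):
            lines.append(f"{CONTIG}\t{s}\t{e}\t{gene.transcript_id}\t{k + 1}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_sex_map(samples: list[tuple[str, str]], path: str | Path) -> None:
    Path(path).write_text("".join(f"{s}\t{sex}\n" for s, sex in samples))


def emit_vcf(
    genes: list[GeneTruth],
    config: SimulationConfig,
    vcf_path: str | Path,
    bed_path: str | Path | None = None,
) -> int:
    """Write a VCF v4.2 of per-base genotypes (monomorphic records included).

    Reference alleles come from the outgroup sequence; males are Z/Z,
    females Z/W (Z/Z for W-deleted genes). Four independent per-record
    corruption modes (low QUAL, one low-DP sample, one missing genotype,
    a spurious third allele) exercise the masking rules downstream.
    Returns the number of records written.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    samples = config.dna_samples()
    n_samples = len(samples)
    total_len = config.gene_length * len(genes)

    header = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={CONTIG},length={total_len}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(s for s, _ in samples),
    ]
    lines = header
    n_records = 0
    for g, gene in enumerate(genes):
        offset = g * config.gene_length
        zseq = gene.seq_Z
        wseq = gene.seq_W if gene.w_present else gene.seq_Z
        for i in range(config.gene_length):
            ref = gene.seq_outgroup[i]
            z, w = zseq[i], wseq[i]
            alleles = [ref]
            for b in (z, w):
                if b not in alleles:
                    alleles.append(b)

            sample_gts: list[list[int] | None] = []
            for _, sex in samples:
                pair = (z, z) if sex == "M" else (z, w)
                sample_gts.append([alleles.index(pair[0]), alleles.index(pair[1])])
            qual = round(float(rng.uniform(30.0, 100.0)), 1)
            dps = rng.poisson(config.mean_depth, size=n_samples)

            # independent corruption modes
            if rng.random() < config.p_low_qual:
                qual = round(float(rng.uniform(0.0, 19.9)), 1)
            if rng.random() < config.p_low_dp:
                dps[int(rng.integers(n_samples))] = int(rng.integers(0, 20))
            if rng.random() < config.p_missing_gt:
                sample_gts[int(rng.integers(n_samples))] = None
            if rng.random() < config.p_triallelic:
                third = [b for b in BASES if b not in alleles]
                if third:
                    extra = third[int(rng.integers(len(third)))]
                    alleles.append(extra)
                    victim = int(rng.integers(n_samples))
                    if sample_gts[victim] is not None:
                        sample_gts[victim][int(rng.integers(2))] = alleles.index(extra)

            alts = alleles[1:]
            alt_field = ",".join(alts) if alts else "."
            fields = [
                CONTIG,
                str(offset + i + 1),
                ".",
                ref,
                alt_field,
                f"{qual:.1f}",
                ".",
                ".",
                "GT:DP",
            ]
            for gt, dp in zip(sample_gts, dps):
                gt_str = "./." if gt is None else f"{gt[0]}/{gt[1]}"
                fields.append(f"{gt_str}:{int(dp)}")
            lines.append("\t".join(fields))
            n_records += 1
    Path(vcf_path).write_text("\n".join(lines) + "\n")
    if bed_path is not None:
        write_bed(genes, config, bed_path)
    return n_records


def emit_dna_coverage(
    genes: list[GeneTruth], config: SimulationConfig
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-exon DNA read counts per sample, plus per-sample library totals.

    Expected read count of an exon is (library multiplier) x (mean depth x
    exon length / read length), halved in females for W-deleted genes.
    Counts are Poisson. Returns (long-format counts, per-sample totals).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    samples = config.dna_samples()
    mult = {s: float(rng.uniform(0.7, 1.3)) for s, _ in samples}
    totals = pd.Series(
        {s: int(round(5_000_000 * mult[s])) for s, _ in samples}, name="total_reads"
    )
    rows = []
    for g, gene in enumerate(genes):
        for k, (start, end) in enumerate(exon_intervals(g, config)):
            length = end - start
            base = config.mean_depth * length / config.read_length
            for s, sex in samples:
                mu = mult[s] * base
                if sex == "F" and not gene.w_present:
                    mu *= 0.5
                rows.append(
                    {
                        "sample": s,
                        "exon_id": f"{gene.transcript_id}.e{k + 1}",
                        "transcript_id": gene.transcript_id,
                        "count": int(rng.poisson(mu)),
                        "exon_length": length,
                    }
                )
    return pd.DataFrame(rows), totals


def emit_expression_counts(
    genes: list[GeneTruth], config: SimulationConfig
) -> tuple[pd.DataFrame, dict[str, str]]:
    """RNA-seq count matrix (genes x samples) under the degeneration link.

    Male mean is expr_mean; female mean is expr_mean x female_expr_ratio,
    where the ratio is 1 - beta_link * min(dN/d_cap, 1) / 2 for W-present
    genes and exactly 0.5 for W-deleted genes (no compensation). Counts are
    negative binomial with variance mu + dispersion * mu^2; per-sample
    library sizes are jittered uniformly in [0.7, 1.3].
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    samples = config.rna_samples()
    libsize = {s: float(rng.uniform(0.7, 1.3)) for s, _ in samples}
    disp = config.expr_dispersion
    data = {}
    for s, sex in samples:
        mus = np.array(
            [
                config.expr_mean
                * libsize[s]
                * (g.female_expr_ratio if sex == "F" else 1.0)
                for g in genes
            ]
        )
        if disp > 0:
            n_param = 1.0 / disp
            p_param = n_param / (n_param + mus)
            data[s] = rng.negative_binomial(n_param, p_param)
        else:
            data[s] = rng.poisson(mus)
    counts = pd.DataFrame(data, index=[g.gene_id for g in genes])
    counts.index.name = "gene_id"
    return counts, dict(samples)


def write_truth(genes: list[GeneTruth], config: SimulationConfig, outdir: str | Path) -> None:
    """Write truth FASTA (outgroup/Z/W) and a truth table TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "truth_sequences.fasta", "w") as fh:
        for gene in genes:
            fh.write(f">{gene.gene_id}|outgroup\n{gene.seq_outgroup}\n")
            fh.write(f">{gene.gene_id}|Z\n{gene.seq_Z}\n")
            if gene.w_present:
                fh.write(f">{gene.gene_id}|W\n{gene.seq_W}\n")
    table = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "transcript_id": [g.transcript_id for g in genes],
            "w_present": [int(g.w_present) for g in genes],
            "true_dN_ZW": [g.true_dN_ZW for g in genes],
            "true_dS_ZW": [g.true_dS_ZW for g in genes],
            "female_expr_ratio": [g.female_expr_ratio for g in genes],
        }
    )
    table.to_csv(outdir / "truth_table.tsv", sep="\t", index=False, float_format="%.8g")
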