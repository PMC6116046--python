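# Methods

## The system being modelled

A neo-sex chromosome arises when an autosome fuses with an ancestral sex
chromosome; once Z–W recombination stops across the fused arm, each gene
exists as a pair of gametologs that evolve independently. The package
analyses three consequences of that arrest in a ZW/ZZ (female/male)
system genotyped against an outgroup reference whose split predates the
recombination arrest: (i) faster functional (non-synonymous) divergence
of the W copy under relaxed purifying selection, (ii) GC erosion of the W
relative to the Z, which still experiences recombination-associated
GC-biased substitution in males, and (iii) declining female expression as
the W copy degenerates, with a hard floor at 50% of male expression when
the W contributes nothing and no compensatory up-regulation exists.

## Phasing model and masking semantics

Each VCF site carries unphased diploid genotypes for n_m males (ZZ) and
n_f females (ZW). Sites failing quality gates are masked over the
reference-allele length: site QUAL < t or any per-sample depth < t
(t = 20 by default, both fields filtered conservatively since either can
flag an unreliable call), any missing genotype, any non-unit allele
length (indels mask but never shift coordinates), or more than two
distinct alleles observed among the samples.

For surviving biallelic sites the W call requires all females to share
one genotype (with two W haplotypes in a 2-female design, any discordance
is evidence of error): identical homozygotes give W directly; identical
heterozygotes are oriented only when every male is homozygous for one of
the two female alleles (that allele is Z-linked, the other is the W).
The Z call is a majority vote over all male alleles plus one Z allele per
female whose W is determined (her non-W allele); ties give N. A female
with an unresolved W never votes, so an uncertain W cannot contaminate
the Z consensus — one consistent reading of a rule table whose source
procedure did not specify the attribution; the audit log records which
rule fired at every site. Raising the quality threshold can only mask
more sites, never unmask (verified as a property test).

## Counting dN/dS

The estimator is the classical codon-counting approach. Sites: for each
codon position, the single-base changes that would create a stop codon
are excluded and the position's one site is split between the remaining
changes by their synonymous fraction, so S + N = 3 exactly per codon;
pair totals average the two sequences. Differences: codons differing at
k positions are resolved by averaging the synonymous/non-synonymous step
counts over all k! orderings, excluding orderings that pass through a
stop codon (if every ordering does, all are kept so the codon still
contributes — an arbitrary but symmetric convention for a vanishingly
rare case). Proportions pS = Sd/S and pN = Nd/N are corrected for
multiple hits with the Jukes–Cantor transform d = −(3/4)·ln(1 − 4p/3);
p ≥ 0.75 flags the gene as saturated and excludes it rather than
producing an undefined rate. The implementation is verified to 1e−9
against an independent brute-force path-enumeration oracle, and is exactly
symmetric in its two inputs.

Codon columns containing N, a gap or a stop in any sequence are removed
before estimation. Transcript filters mirror a conservative analysis:
≥500 bp of retained alignment, Z–W dS ≥ 0.01 (counting estimates need
some divergence to be informative; this replaces the likelihood-score
filter an ML estimator would use), longest transcript per gene.

## Coverage-based hemizygosity detection

Per-sample coverage is normalized by total aligned reads (factor =
largest library / sample library), per-exon depth is count/length, and a
transcript's value is the unweighted mean over its exons. A transcript is
called W-absent when female mean coverage is strictly below 70% of the
male mean — halfway between the expectations for two copies (ratio 1) and
one copy (ratio 0.5), with headroom for Poisson noise at 30× depth. The
boundary retains (a ratio of exactly 0.70 passes).

## Expression testing

Size factors are DESeq-style median-of-ratios over genes with nonzero
counts in every sample. Each gene gets a two-group negative-binomial
model: group means from normalized counts (pseudocount 0.5 for sparse
data), one pooled within-group method-of-moments dispersion per gene
α = (var − μ)/μ² floored at 1e−8, Wald statistic log2fc/se with the
delta-method standard error, and a two-sided p from a Student-t reference
with n_F + n_M − 2 degrees of freedom. The t reference (rather than
normal) matters: with a plug-in dispersion from 6+6 replicates the normal
reference rejects 7–9% of null genes at α = 0.05, while t(10) restores
the nominal 5% and raw-p uniformity — the property the null-calibration
tests guard. No empirical-Bayes dispersion shrinkage is applied; this is
a deliberate simplification of the standard NB Wald workflow, guarded by
the null-calibration property instead. Genes with an all-zero sex are
reported with infinite fold change and excluded from testing; BH step-up
adjustment is applied to the testable genes.

Median-of-ratios normalization assumes the typical gene is unshifted
between groups. Whenever a count matrix covers only sex-linked genes,
the inferred factors absorb the average female reduction and log2 ratios
become relative to that baseline; analyses that need absolute ratios
(e.g. the 50% dosage baseline) therefore embed the affected genes in a
majority of unaffected background genes, as a real whole-transcriptome
matrix does.

## The synthetic generator

Ancestral coding sequences (ATG + random sense codons) evolve along the
three-taxon topology: outgroup branch t_outgroup; shared proto-gametolog
branch t_outgroup − t_sexlinked; then Z and W branches of t_sexlinked
each. Branch lengths are expected substitution proposals per site — the
neutral divergence scale, so realized dS per synonymous site ≈ branch
length and realized dN ≈ ω × branch length. Each proposal picks a site
uniformly and a target base with transition weight κ (default 2) and, on
the Z branch only, weight gc_bias_Z on A/T→G/C changes; proposals
creating stops are rejected, synonymous proposals always accepted,
non-synonymous ones with probability ω of the lineage (outgroup and proto
branches use ω_Z, the background purifying regime; ω_W models relaxation
after recombination arrest). Every accepted substitution is logged, and
per-gene true dN/dS are computed from those events against the site
counts of the proto sequence — the oracle the estimator tests recover.

Defaults mirror the modelled system: t_sexlinked = 0.025 and t_outgroup =
0.029 give Z–W dS ≈ 0.05 with the outgroup split slightly older than the
recombination arrest (the 22 vs 19 My chronology); ω_Z = 0.1, ω_W = 0.5.
Genes receive a lognormal rate multiplier (log-sd 1, clipped to [0.1,
10]) applied to all branches, reproducing the roughly two-orders-of-
magnitude between-gene dS spread real gametolog sets show; without it,
between-gene divergence variation is pure Poisson noise and the
GC-ratio-vs-divergence correlation cannot exist at any bias strength.
A configuration whose expected pairwise divergence exceeds dS = 1.5 is
rejected (saturation guard).

The VCF emitter writes one record per reference base (monomorphic records
included) with males Z/Z, females Z/W (Z/Z where the W is deleted), QUAL
~ U(30, 100) and per-sample depth ~ Poisson(mean_depth = 30). Four
independent per-record corruption modes — low QUAL, one low-depth sample,
one missing genotype, a spurious third allele — each default to 1.25%
(5% total) and exercise one masking rule each. Exons are deterministic
equal thirds (remainder to the last), so BED fixtures are reproducible.
DNA coverage counts are Poisson with per-sample library multipliers
~ U(0.7, 1.3), halved in females for W-deleted genes. Expression counts
are negative binomial (dispersion 0.05) at mean 500, with female mean
scaled by the link ratio 1 − β·min(dN/d_cap, 1)/2 for W-present genes and
exactly 0.5 for W-deleted genes. d_cap = 0.02 — about twice the median
neo-sex dN the modelled system shows — is the functional divergence at
which the W copy is treated as fully silenced; at full coupling (β = 1)
this yields expression–dN rank correlations around −0.5 at realistic
noise, a sensible strongest-coupling endpoint given that partially
coupled real data already show ≈ −0.33. All randomness flows from a
single seed through named substreams per stage, so every artifact is
byte-identical across reruns.

What the generator does not emulate: within-species polymorphism and
genotyping error (genotypes are exact given the haplotypes, so phasing
recovery measures masking behaviour, not caller error), indels and
alignment uncertainty, read-level artefacts, linked selection, and any
correlation structure between genes beyond the shared library sizes.
Passing tests therefore demonstrate correctness of the inference chain
under the stated model, not robustness to upstream artefacts.

## Statistical conventions

Ties by average rank throughout. Spearman p-values use the t
approximation with n − 2 df; an exact permutation null is available for
n ≤ 10. Signed-rank tests drop zero differences and use the exact null
for ≤ 25 untied differences, otherwise the tie-corrected normal
approximation; rank-sum tests use the tie-corrected normal approximation;
paired and Welch t-tests are two-sided. Statistical machinery is backed
by scipy/statsmodels; small-n enumeration oracles in the test suite
verify the conventions.

## Validation harness sizes

The acceptance-style tests run at sizes chosen to finish in minutes on
one core while keeping each effect comfortably detectable: the 50%
dosage baseline on ~1000 silenced genes in a 34,000-gene background
(silenced fraction 3%, keeping the normalization reference unbiased);
phasing recovery on 50 genes × 500 codons at 5% corruption; the
relaxed-selection outgroup contrast on 20 seeds × 200 genes under
homogeneous rates (the paired-t on dS assumes comparable per-gene
variances, which the lognormal rate spread deliberately violates); FDR
calibration on 20 × 2,000 null genes; the expression–divergence link at
64 genes per seed (a neo-sex-chromosome-sized gene set); and the GC
analyses at 400 genes with gc_bias_Z = 6, the strong-conversion condition
under which a 20-My-scale branch produces the GC gap the modelled system
exhibits.

## Known limitations

The phasing rule table generalizes to any ≥1 males + ≥1 females but its
confidence argument (only two W haplotypes sampled) weakens with more
females. The counting dN/dS estimator is biased at very low divergence
(hence the dS ≥ 0.01 filter) and ignores codon-frequency and
transition/transversion structure that ML estimators model; ω from the
Z–W pair mixes the two lineages (the outgroup contrast separates them).
The NB test uses per-gene plug-in dispersions and will be underpowered
relative to shrinkage-based methods at these replicate numbers. The 50%
dosage floor measured through whole-matrix normalization carries a small
upward bias (~1 point) from the silenced minority's pull on the size
factors plus Jensen's inequality on the per-gene ratio; both are inherent
to the measurement design, not errors.
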