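"""Gametolog phasing from sex-labelled diploid genotypes.

Converts a VCF of ZZ males and ZW females, called against an outgroup
reference, into per-transcript Z and W nucleotide sequences. Each site is
resolved by a fixed rule table; anything the rules cannot resolve safely
is masked with N rather than guessed.

Rule order per site (defaults follow the quality conventions of short-read
genotype callers):

1. site QUAL < threshold, any sample depth < threshold, or any genotype
   missing -> both alleles masked over the reference-allele length;
2. any allele of non-unit length (indel) -> both masked over the
   reference-allele length;
3. more than two distinct alleles observed among the samples -> both masked;
4. W call: all females must share the same genotype ("no difference between
   the female genotypes" -- there are only two W haplotypes in a 2F
   design). Identical homozygous females give W directly; identical
   heterozygous females give W only when every male is homozygous for one
   of the two female alleles (the shared allele is then Z-linked, the
   other is the W allele). Discordant or unresolvable females leave W = N.
5. Z call: majority vote over all male alleles (two per male) plus one
   Z allele per female whose W call is determined (a female contributes
   her non-W allele; a homozygous female her only allele). A tied vote
   leaves Z = N. Females with an undetermined W never vote, so an
   unresolved W cannot contaminate the Z consensus.

With 2 males and 2 females this reproduces the published truth table: hom
males + het females orient Z to the shared allele and W to the other, in
both reference/variant orientations; monomorphic records return the
reference for both.
"""

from __future__ import annotations

from bisect import bisect_right
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from cyvcf2 import VCF

MASK_NONE = "none"
FULL_MASK_REASONS = ("low_qual", "low_depth", "missing_gt", "multiallelic", "indel")


@dataclass
class VariantSite:
    """One VCF record with sex-labelled genotypes."""

    contig: str
    pos: int                      # 1-based
    ref: str
    alts: list[str]
    qual: float | None
    genotypes: list[tuple[int, int] | None]   # unphased allele-index pairs
    depths: list[int | None]
    sexes: list[str]              # 'M' or 'F', aligned with genotypes

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        n = len(self.genotypes)
        if not (len(self.depths) == len(self.sexes) == n):
            raise ValueError(
                f"{self.contig}:{self.pos}: genotype/depth/sex lengths differ"
            )
        if "M" not in self.sexes or "F" not in self.sexes:
            raise ValueError(f"{self.contig}:{self.pos}: need >=1 sample of each sex")


@dataclass
class SiteCall:
    z_allele: str
    w_allele: str
    rule_id: str
    mask_reason: str = MASK_NONE
    span: int = 1                 # number of reference bases masked/called


@dataclass
class PhasedGametolog:
    transcript_id: str
    z_seq: str
    w_seq: str
    n_sites_called: int
    n_sites_masked: int
    mask_reasons: Counter = field(default_factory=Counter)
    rules: Counter = field(default_factory=Counter)


def _allele(site: VariantSite, index: int) -> str:
    return site.ref if index == 0 else site.alts[index - 1]


def classify_site(site: VariantSite, min_qual_depth: float = 20) -> SiteCall:
    """Resolve one site into Z and W alleles (or N) per the rule table."""
    span = len(site.ref)

    if site.qual is None or site.qual < min_qual_depth:
        return SiteCall("N", "N", "filtered", "low_qual", span)
    if any(d is None or d < min_qual_depth for d in site.depths):
        return SiteCall("N", "N", "filtered", "low_depth", span)
    if any(g is None for g in site.genotypes):
        return SiteCall("N", "N", "filtered", "missing_gt", span)

    try:
        observed_idx = sorted({i for g in site.genotypes for i in g})
        alleles = {i: _allele(site, i) for i in observed_idx}
    except IndexError:
        raise ValueError(
            f"{site.contig}:{site.pos}: genotype refers to an undeclared allele"
        ) from None
    if any(len(a) != 1 for a in alleles.values()) or len(site.ref) != 1:
        return SiteCall("N", "N", "filtered", "indel", span)
    if len(set(alleles.values())) > 2:
        return SiteCall("N", "N", "filtered", "multiallelic", span)

    male_gts = [g for g, s in zip(site.genotypes, site.sexes) if s == "M"]
    female_gts = [g for g, s in zip(site.genotypes, site.sexes) if s == "F"]

    # ---- W call, and each female's attributable Z allele -------------
    w_allele = "N"
    w_reason = MASK_NONE
    female_z_votes: list[int] = []
    female_sets = {frozenset(g) for g in female_gts}
    if len(female_sets) > 1:
        w_reason = "female_discordant"
    else:
        fg = female_gts[0]
        if fg[0] == fg[1]:  # identical homozygous females
            w_allele = alleles[fg[0]]
            female_z_votes = [fg[0]] * len(female_gts)
        else:  # identical heterozygous females: need hom males to orient
            male_hom = {g[0] for g in male_gts if g[0] == g[1]}
            shared = male_hom & set(fg) if len(male_hom) == 1 and all(
                g[0] == g[1] for g in male_gts
            ) else set()
            if shared:
                z_idx = next(iter(shared))
                w_idx = fg[0] if fg[1] == z_idx else fg[1]
                w_allele = alleles[w_idx]
                female_z_votes = [z_idx] * len(female_gts)
            else:
                w_reason = "ambiguous"

    # ---- Z call: majority vote ---------------------------------------
    votes = Counter(i for g in male_gts for i in g)
    votes.update(female_z_votes)
    ranked = votes.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        z_allele = "N"
    else:
        z_allele = alleles[ranked[0][0]]

    # ---- audit labels ------------------------------------------------
    if z_allele == "N" and w_allele == "N":
        reason = w_reason if w_reason != MASK_NONE else "z_tie"
        return SiteCall("N", "N", "unresolved", reason, span)
    if w_allele == "N":
        return SiteCall(z_allele, "N", "partial", w_reason, span)
    if z_allele == "N":
        return SiteCall("N", w_allele, "partial", "z_tie", span)

    gt_all = [tuple(sorted(g)) for g in site.genotypes]
    if all(g == (0, 0) for g in gt_all):
        rule = "monomorphic"
    elif all(g[0] == g[1] for g in male_gts) and female_gts[0][0] != female_gts[0][1]:
        rule = "male_hom_female_het"
    elif all(g[0] == g[1] for g in gt_all):
        rule = "all_hom" if z_allele == w_allele else "hom_by_sex"
    else:
        rule = "consensus"
    return SiteCall(z_allele, w_allele, rule, MASK_NONE, span)


@dataclass
class _TranscriptBuffer:
    transcript_id: str
    exons: list[tuple[int, int]]          # 0-based half-open, sorted
    z: list[str] = field(default_factory=list)
    w: list[str] = field(default_factory=list)
    reasons: Counter = field(default_factory=Counter)
    rules: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        length = sum(e - s for s, e in self.exons)
        self.z = ["N"] * length
        self.w = ["N"] * length
        self._starts = [s for s, _ in self.exons]
        self._offsets = []
        off = 0
        for s, e in self.exons:
            self._offsets.append(off)
            off += e - s

    def index_of(self, pos0: int) -> int | None:
        """Transcript index of a 0-based contig position, or None."""
        k = bisect_right(self._starts, pos0) - 1
        if k < 0:
            return None
        s, e = self.exons[k]
        if pos0 >= e:
            return None
        return self._offsets[k] + (pos0 - s)

    def apply(self, pos0: int, call: SiteCall) -> None:
        for p in range(pos0, pos0 + call.span):
            idx = self.index_of(p)
            if idx is None:
                continue
            self.z[idx] = call.z_allele if call.span == 1 else "N"
            self.w[idx] = call.w_allele if call.span == 1 else "N"
            if call.span > 1:
                self.reasons[call.mask_reason] += 1
            else:
                if call.mask_reason != MASK_NONE:
                    self.reasons[call.mask_reason] += 1
                self.rules[call.rule_id] += 1

    def finish(self) -> PhasedGametolog:
        z_seq = "".join(self.z)
        w_seq = "".join(self.w)
        n_masked = sum(1 for a, b in zip(z_seq, w_seq) if a == "N" or b == "N")
        return PhasedGametolog(
            transcript_id=self.transcript_id,
            z_seq=z_seq,
            w_seq=w_seq,
            n_sites_called=len(z_seq) - n_masked,
            n_sites_masked=n_masked,
            mask_reasons=self.reasons,
            rules=self.rules,
        )


def read_bed_transcripts(bed_path: str | Path) -> dict[str, list[tuple[str, int, int]]]:
    """Parse a BED3+name file into transcript -> [(contig, start, end)]."""
    transcripts: dict[str, list[tuple[str, int, int]]] = {}
    for line in Path(bed_path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise ValueError(f"BED line lacks a name column: {line!r}")
        contig, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
        transcripts.setdefault(name, []).append((contig, start, end))
    for name, exons in transcripts.items():
        exons.sort(key=lambda x: (x[0], x[1]))
        contigs = {c for c, _, _ in exons}
        if len(contigs) > 1:
            raise ValueError(f"transcript {name} spans multiple contigs")
        for (_, s1, e1), (_, s2, _) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(f"transcript {name} has overlapping exons")
    return transcripts


def read_sex_map(path: str | Path) -> dict[str, str]:
    sexes = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        sample, sex = line.split("\t")
        if sex not in ("M", "F"):
            raise ValueError(f"sex must be M or F, got {sex!r} for {sample}")
        sexes[sample] = sex
    return sexes


def phase_transcript(
    sites: Iterable[VariantSite],
    exons: list[tuple[int, int]],
    transcript_id: str = "transcript",
    min_qual_depth: float = 20,
) -> PhasedGametolog:
    """Phase one transcript from an iterable of sites on its contig.

    Exon coordinates are 0-based half-open; positions without a record
    remain N.
    """
    buf = _TranscriptBuffer(transcript_id, sorted(exons))
    for site in sites:
        call = classify_site(site, min_qual_depth)
        buf.apply(site.pos - 1, call)
    return buf.finish()


def _sites_from_vcf(
    vcf_path: str | Path, sex_map: dict[str, str]
) -> Iterator[VariantSite]:
    vcf = VCF(str(vcf_path), gts012=False)
    samples = vcf.samples
    missing = [s for s in samples if s not in sex_map]
    if missing:
        raise ValueError(f"samples missing from sex map: {missing}")
    sexes = [sex_map[s] for s in samples]
    for v in vcf:
        gts = []
        for g in v.genotypes:
            a, b = g[0], g[1]
            gts.append(None if a < 0 or b < 0 else (a, b))
        dp = v.format("DP")
        if dp is None:
            depths: list[int | None] = [None] * len(samples)
        else:
            depths = [int(d) if d >= 0 else None for d in dp[:, 0]]
        yield VariantSite(
            contig=v.CHROM,
            pos=v.POS,
            ref=v.REF,
            alts=list(v.ALT),
            qual=v.QUAL,
            genotypes=gts,
            depths=depths,
            sexes=sexes,
        )


def phase_vcf(
    vcf_path: str | Path,
    bed_path: str | Path,
    sex_map: dict[str, str],
    min_qual_depth: float = 20,
) -> dict[str, PhasedGametolog]:
    """Phase every transcript in a BED file from a sorted VCF."""
    transcripts = read_bed_transcripts(bed_path)
    buffers: dict[str, _TranscriptBuffer] = {}
    by_contig: dict[str, list[tuple[int, int, str]]] = {}
    for tid, exons in transcripts.items():
        contig = exons[0][0]
        buffers[tid] = _TranscriptBuffer(tid, [(s, e) for _, s, e in exons])
        for _, s, e in exons:
            by_contig.setdefault(contig, []).append((s, e, tid))
    for intervals in by_contig.values():
        intervals.sort()

    for site in _sites_from_vcf(vcf_path, sex_map):
        intervals = by_contig.get(site.contig)
        if not intervals:
            continue
        pos0 = site.pos - 1
        starts = [s for s, _, _ in intervals]
        k = bisect_right(starts, pos0) - 1
        hits = set()
        # an indel span can touch the next interval as well
        for j in (k, k + 1):
            if 0 <= j < len(intervals):
                s, e, tid = intervals[j]
                if pos0 < e and pos0 + len(site.ref) > s:
                    hits.add(tid)
        if not hits:
            continue
        call = classify_site(site, min_qual_depth)
        for tid in hits:
            buffers[tid].apply(pos0, call)
    return {tid: buf.finish() for tid, buf in buffers.items()}


def write_phased_fasta(
    phased: dict[str, PhasedGametolog], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for tid in sorted(phased):
            p = phased[tid]
            fh.write(f">{tid}|Z\n{p.z_seq}\n>{tid}|W\n{p.w_seq}\n")


def write_audit_table(phased: dict[str, PhasedGametolog], path: str | Path) -> None:
    reasons = sorted({r for p in phased.values() for r in p.mask_reasons})
    header = ["transcript_id", "length", "n_called", "n_masked"] + reasons
    lines = ["\t".join(header)]
    for tid in sorted(phased):
        p = phased[tid]
        row = [tid, str(len(p.z_seq)), str(p.n_sites_called), str(p.n_sites_masked)]
        row += [str(p.mask_reasons.get(r, 0)) for r in reasons]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")
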