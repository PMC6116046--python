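"""Site classification rules and transcript assembly."""

from itertools import product

import pytest

from neosex.phasing import (
    FULL_MASK_REASONS,
    MASK_NONE,
    PhasedGametolog,
    SiteCall,
    VariantSite,
    classify_site,
    phase_transcript,
)


def _site(male_gts, female_gts, ref="A", alts=("G",), qual=50.0, dp=30):
    gts = list(male_gts) + list(female_gts)
    return VariantSite(
        contig="chr1",
        pos=100,
        ref=ref,
        alts=list(alts),
        qual=qual,
        genotypes=gts,
        depths=[dp] * len(gts),
        sexes=["M"] * len(male_gts) + ["F"] * len(female_gts),
    )


# ---------------------------------------------------------------------------
# published rule-table rows
# ---------------------------------------------------------------------------

def test_hom_ref_males_het_females_give_z_ref_w_alt():
    call = classify_site(_site([(0, 0), (0, 0)], [(0, 1), (0, 1)]))
    assert (call.z_allele, call.w_allele) == ("A", "G")
    assert call.mask_reason == MASK_NONE


def test_hom_alt_males_het_females_give_z_alt_w_ref():
    call = classify_site(_site([(1, 1), (1, 1)], [(0, 1), (0, 1)]))
    assert (call.z_allele, call.w_allele) == ("G", "A")


def test_low_quality_masks_both_alleles():
    call = classify_site(_site([(0, 0), (0, 0)], [(0, 1), (0, 1)], qual=15.0))
    assert (call.z_allele, call.w_allele) == ("N", "N")
    assert call.mask_reason == "low_qual"


def test_low_depth_in_any_sample_masks_both_alleles():
    site = _site([(0, 0), (0, 0)], [(0, 1), (0, 1)])
    site.depths[2] = 19
    call = classify_site(site)
    assert call.mask_reason == "low_depth"
    assert (call.z_allele, call.w_allele) == ("N", "N")


def test_missing_genotype_masks_both_alleles():
    call = classify_site(_site([(0, 0), None], [(0, 1), (0, 1)]))
    assert call.mask_reason == "missing_gt"


def test_discordant_females_mask_w_but_not_z():
    call = classify_site(_site([(0, 0), (0, 0)], [(0, 1), (0, 0)]))
    assert call.w_allele == "N"
    assert call.mask_reason == "female_discordant"
    assert call.z_allele == "A"


def test_three_observed_alleles_mask_both():
    call = classify_site(
        _site([(0, 0), (1, 1)], [(0, 2), (0, 2)], alts=("G", "T"))
    )
    assert call.mask_reason == "multiallelic"
    assert (call.z_allele, call.w_allele) == ("N", "N")


def test_monomorphic_record_returns_reference_for_both():
    call = classify_site(_site([(0, 0), (0, 0)], [(0, 0), (0, 0)], alts=()))
    assert (call.z_allele, call.w_allele) == ("A", "A")
    assert call.rule_id == "monomorphic"


def test_indel_masks_reference_length_span():
    call = classify_site(
        _site([(0, 0), (0, 0)], [(0, 1), (0, 1)], ref="ATT", alts=("A",))
    )
    assert call.mask_reason == "indel"
    assert call.span == 3


def test_hom_by_sex_orients_z_to_males():
    call = classify_site(_site([(0, 0), (0, 0)], [(1, 1), (1, 1)]))
    assert (call.z_allele, call.w_allele) == ("A", "G")


def test_all_hom_alt_gives_alt_for_both():
    call = classify_site(_site([(1, 1), (1, 1)], [(1, 1), (1, 1)]))
    assert (call.z_allele, call.w_allele) == ("G", "G")


# ---------------------------------------------------------------------------
# exhaustive truth table vs an independently written rule oracle
# ---------------------------------------------------------------------------

def _rule_oracle(m1, m2, f1, f2, ref="A", alt="G"):
    """Literal transcription of the ordered rule rows for a clean biallelic
    site: monomorphic, hom-male/het-female orientation, sex-homozygote rows,
    female concordance requirement, and the male+attributable-female Z
    consensus with ties masked."""
    allele = {0: ref, 1: alt}
    males = [tuple(sorted(g)) for g in (m1, m2)]
    females = [tuple(sorted(g)) for g in (f1, f2)]

    if males == [(0, 0)] * 2 and females == [(0, 0)] * 2:
        return ref, ref
    # identical het females oriented by uniformly homozygous males
    if females[0] == females[1]:
        fa, fb = females[0]
        if fa != fb and males[0] == males[1] and males[0][0] == males[0][1]:
            c = males[0][0]
            if c in (fa, fb):
                w = fb if c == fa else fa
                z_votes = [c] * 6
                return allele[c], allele[w]

    # W allele
    w_allele = None
    female_z = []
    if females[0] == females[1]:
        fa, fb = females[0]
        if fa == fb:
            w_allele = fa
            female_z = [fa, fa]
    # Z consensus: 4 male alleles + attributable female alleles
    votes = [a for g in males for a in g] + female_z
    counts = {i: votes.count(i) for i in set(votes)}
    best = sorted(counts.items(), key=lambda kv: -kv[1])
    if len(best) > 1 and best[0][1] == best[1][1]:
        z = "N"
    else:
        z = allele[best[0][0]]
    w = "N" if w_allele is None else allele[w_allele]
    return z, w


@pytest.mark.parametrize(
    "config", list(product([(0, 0), (0, 1), (1, 1)], repeat=4))
)
def test_exhaustive_genotype_truth_table(config):
    m1, m2, f1, f2 = config
    call = classify_site(_site([m1, m2], [f1, f2]))
    assert (call.z_allele, call.w_allele) == _rule_oracle(m1, m2, f1, f2)


def test_full_mask_reasons_mask_both_alleles():
    cases = {
        "low_qual": _site([(0, 0), (0, 0)], [(0, 1), (0, 1)], qual=5.0),
        "missing_gt": _site([None, (0, 0)], [(0, 1), (0, 1)]),
        "multiallelic": _site([(0, 0), (1, 1)], [(2, 2), (2, 2)], alts=("G", "T")),
        "indel": _site([(0, 0), (0, 0)], [(0, 1), (0, 1)], alts=("GT",)),
    }
    for reason, site in cases.items():
        call = classify_site(site)
        assert call.mask_reason == reason
        assert call.z_allele == "N" and call.w_allele == "N"
        assert reason in FULL_MASK_REASONS


def test_raising_threshold_never_unmasks():
    sites = [
        _site([(0, 0), (0, 0)], [(0, 1), (0, 1)], qual=q, dp=d)
        for q in (10, 25, 60)
        for d in (10, 25, 60)
    ]
    for site in sites:
        lo = classify_site(site, min_qual_depth=20)
        hi = classify_site(site, min_qual_depth=40)
        if lo.z_allele == "N":
            assert hi.z_allele == "N"
        if lo.w_allele == "N":
            assert hi.w_allele == "N"


def test_malformed_genotype_reports_coordinates():
    site = _site([(0, 5), (0, 0)], [(0, 1), (0, 1)])
    with pytest.raises(ValueError, match="chr1:100"):
        classify_site(site)


# ---------------------------------------------------------------------------
# transcript assembly
# ---------------------------------------------------------------------------

def _mono_site(pos, ref="C"):
    return VariantSite(
        contig="chr1",
        pos=pos,
        ref=ref,
        alts=[],
        qual=50.0,
        genotypes=[(0, 0)] * 4,
        depths=[30] * 4,
        sexes=["M", "M", "F", "F"],
    )


def test_phase_transcript_concatenates_exons_and_masks_gaps():
    # exon [0,5) and [8,13): 10 bases total; records at 1..4 and 9..13 only
    sites = [_mono_site(p) for p in (1, 2, 3, 4, 9, 10, 11, 12, 13)]
    phased = phase_transcript(sites, [(0, 5), (8, 13)], "t1")
    assert len(phased.z_seq) == 10
    assert phased.z_seq == "CCCC" + "N" + "C" * 5
    assert phased.w_seq == phased.z_seq
    assert phased.n_sites_masked == 1
    assert phased.n_sites_called == 9


def test_phase_transcript_counts_masked_records():
    sites = [_mono_site(p) for p in range(1, 11)]
    sites[3] = _site([(0, 0), (0, 0)], [(0, 1), (0, 1)], qual=5.0)
    sites[3].pos = 4
    sites[7] = _site([(0, 0), (0, 0)], [(0, 1), (0, 0)])
    sites[7].pos = 8
    phased = phase_transcript(sites, [(0, 10)], "t1")
    assert phased.z_seq.count("N") == 1          # low qual masks Z too
    assert phased.w_seq.count("N") == 2          # plus the discordant females
    assert phased.mask_reasons["low_qual"] == 1
    assert phased.mask_reasons["female_discordant"] == 1


def test_records_outside_exons_are_ignored():
    sites = [_mono_site(p) for p in (1, 2, 50)]
    phased = phase_transcript(sites, [(0, 2)], "t1")
    assert phased.z_seq == "CC"
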