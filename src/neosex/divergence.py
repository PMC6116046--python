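"""Codon-level divergence between gametologs and against an outgroup.

dN and dS are estimated by codon counting: synonymous and non-synonymous
site fractions per codon (with stop-neighbour renormalization), observed
differences resolved by averaging over all minimal substitution paths
(paths through stop codons excluded), proportions corrected for multiple
hits with the Jukes-Cantor formula. This is the classical counting
alternative to ML codon models: closed-form, symmetric in its inputs, and
exactly checkable by exhaustive enumeration.

GC content is computed over the retained alignment columns, and the Z/W
GC ratio indexes the erosion of GC on the non-recombining W.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .codon import BASES, CODON_TO_AA, is_stop, ng86_sites

SATURATION_P = 0.75


@dataclass
class CodonAlignment:
    """Equal-length coding sequences after codon masking."""

    gene_id: str
    seqs: dict[str, str]            # label -> retained sequence
    n_codons_retained: int
    n_codons_dropped: int


@dataclass
class DivergenceEstimate:
    gene_id: str
    pair: str
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    ps: float
    pn: float
    ds: float
    dn: float
    omega: float                    # NaN when dS == 0
    saturated: bool = False         # pS or pN at/beyond the JC bound


def mask_codons(seqs: dict[str, str], gene_id: str = "") -> CodonAlignment:
    """Drop every codon column containing N, a gap, or a stop in any sequence."""
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError(f"{gene_id}: sequences have unequal lengths {lengths}")
    (length,) = lengths
    if length % 3:
        raise ValueError(f"{gene_id}: alignment length {length} not divisible by 3")
    labels = list(seqs)
    kept: dict[str, list[str]] = {lab: [] for lab in labels}
    dropped = 0
    for c in range(length // 3):
        codons = {lab: seqs[lab][3 * c : 3 * c + 3].upper() for lab in labels}
        bad = any(
            any(b not in BASES for b in codon) or is_stop(codon)
            for codon in codons.values()
        )
        if bad:
            dropped += 1
            continue
        for lab in labels:
            kept[lab].append(codons[lab])
    return CodonAlignment(
        gene_id=gene_id,
        seqs={lab: "".join(cs) for lab, cs in kept.items()},
        n_codons_retained=length // 3 - dropped,
        n_codons_dropped=dropped,
    )


def _path_differences(c1: str, c2: str) -> tuple[float, float]:
    """Mean synonymous and non-synonymous step counts between two codons.

    Averages over all orderings of the differing positions; orderings that
    pass through a stop codon are excluded (unless every ordering does, in
    which case stops are tolerated so the codon still contributes).
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0

    def walk(allow_stops: bool) -> list[tuple[int, int]]:
        out = []
        for order in permutations(diff):
            cur = c1
            s = n = 0
            ok = True
            for p in order:
                nxt = cur[:p] + c2[p] + cur[p + 1 :]
                if is_stop(nxt) and nxt != c2 and not allow_stops:
                    ok = False
                    break
                if CODON_TO_AA[nxt] == CODON_TO_AA[cur]:
                    s += 1
                else:
                    n += 1
                cur = nxt
            if ok:
                out.append((s, n))
        return out

    paths = walk(allow_stops=False)
    if not paths:
        paths = walk(allow_stops=True)
    s_mean = sum(p[0] for p in paths) / len(paths)
    n_mean = sum(p[1] for p in paths) / len(paths)
    return s_mean, n_mean


def _jc_correct(p: float) -> float:
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def pairwise_dnds(
    seq1: str, seq2: str, gene_id: str = "", pair: str = ""
) -> DivergenceEstimate:
    """Counting dN/dS for a pre-masked pair of coding sequences."""
    if len(seq1) != len(seq2):
        raise ValueError(f"{gene_id}: unequal sequence lengths")
    if not seq1 or len(seq1) % 3:
        raise ValueError(f"{gene_id}: need a non-empty in-frame alignment")
    n_codons = len(seq1) // 3
    s_sites = n_sites = 0.0
    sd = nd = 0.0
    for c in range(n_codons):
        c1 = seq1[3 * c : 3 * c + 3]
        c2 = seq2[3 * c : 3 * c + 3]
        s1, n1 = ng86_sites(c1)
        s2, n2 = ng86_sites(c2)
        s_sites += (s1 + s2) / 2.0
        n_sites += (n1 + n2) / 2.0
        s_diff, n_diff = _path_differences(c1, c2)
        sd += s_diff
        nd += n_diff
    ps = sd / s_sites if s_sites else 0.0
    pn = nd / n_sites if n_sites else 0.0
    saturated = ps >= SATURATION_P or pn >= SATURATION_P
    ds = _jc_correct(ps) if not saturated else float("nan")
    dn = _jc_correct(pn) if not saturated else float("nan")
    omega = dn / ds if ds and ds > 0 else float("nan")
    return DivergenceEstimate(
        gene_id=gene_id,
        pair=pair,
        s_sites=s_sites,
        n_sites=n_sites,
        sd=sd,
        nd=nd,
        ps=ps,
        pn=pn,
        ds=ds,
        dn=dn,
        omega=omega,
        saturated=saturated,
    )


def estimates_table(estimates: list[DivergenceEstimate]) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in estimates])


def outgroup_contrast(estimates: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Paired per-gene Z-vs-outgroup and W-vs-outgroup rates, with tests.

    Input is a tidy estimates table with columns gene_id, pair, dn, ds
    containing pairs 'Z-outgroup' and 'W-outgroup'. Genes missing either
    pair (e.g. no outgroup, saturated) are excluded and counted. Paired
    t-tests ask whether W has diverged more than Z from the outgroup --
    for dN this is the signature of relaxed selection on the
    non-recombining W; for dS the difference should vanish, because both
    gametologs share the same time depth to the outgroup.
    """
    z = estimates[estimates["pair"] == "Z-outgroup"].set_index("gene_id")
    w = estimates[estimates["pair"] == "W-outgroup"].set_index("gene_id")
    shared = z.index.intersection(w.index)
    paired = pd.DataFrame(
        {
            "dn_z_out": z.loc[shared, "dn"],
            "dn_w_out": w.loc[shared, "dn"],
            "ds_z_out": z.loc[shared, "ds"],
            "ds_w_out": w.loc[shared, "ds"],
        }
    ).dropna()
    n_excluded = len(set(z.index) | set(w.index)) - len(paired)
    tests = {"n_genes": len(paired), "n_excluded": int(n_excluded)}
    for metric in ("dn", "ds"):
        a = paired[f"{metric}_w_out"]
        b = paired[f"{metric}_z_out"]
        if len(paired) >= 2:
            t, p = stats.ttest_rel(a, b)
        else:
            t, p = float("nan"), float("nan")
        tests[metric] = {
            "mean_w_out": float(a.mean()) if len(a) else float("nan"),
            "mean_z_out": float(b.mean()) if len(b) else float("nan"),
            "t": float(t),
            "p": float(p),
        }
    return paired.reset_index(), tests


@dataclass
class GCStat:
    gene_id: str
    gc_Z: float
    gc_W: float
    gc_outgroup: float | None
    gc_ratio_ZW: float              # NaN when gc_W == 0


def _gc_percent(seq: str) -> float:
    if not seq:
        raise ValueError("empty sequence")
    return 100.0 * sum(1 for b in seq if b in "GC") / len(seq)


def gc_stats(alignment: CodonAlignment) -> GCStat:
    """Percent GC per retained sequence and the Z/W ratio."""
    if alignment.n_codons_retained == 0:
        raise ValueError(f"{alignment.gene_id}: empty alignment")
    gc = {lab: _gc_percent(s) for lab, s in alignment.seqs.items()}
    gc_z, gc_w = gc["Z"], gc["W"]
    ratio = gc_z / gc_w if gc_w > 0 else float("nan")
    return GCStat(
        gene_id=alignment.gene_id,
        gc_Z=gc_z,
        gc_W=gc_w,
        gc_outgroup=gc.get("outgroup"),
        gc_ratio_ZW=ratio,
    )


def select_transcripts(
    table: pd.DataFrame,
    min_length_bp: int = 500,
    min_ds: float = 0.01,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the transcript-selection filters.

    ``table`` needs columns gene_id, transcript_id, retained_bp and ds
    (the Z-W synonymous rate). Drops transcripts shorter than
    ``min_length_bp`` of retained alignment, transcripts with
    ds < ``min_ds`` (counting estimates need some divergence to be
    informative), then keeps the longest transcript per gene. Returns the
    filtered table and per-filter removal counts.
    """
    counts = {"input": len(table)}
    t = table[table["retained_bp"] >= min_length_bp]
    counts["removed_short"] = counts["input"] - len(t)
    t2 = t[t["ds"] >= min_ds]
    counts["removed_low_ds"] = len(t) - len(t2)
    t3 = (
        t2.sort_values(["gene_id", "retained_bp", "transcript_id"],
                       ascending=[True, False, True])
        .groupby("gene_id", sort=True)
        .head(1)
        .reset_index(drop=True)
    )
    counts["removed_shorter_isoform"] = len(t2) - len(t3)
    counts["retained"] = len(t3)
    return t3, counts
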