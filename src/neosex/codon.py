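"""Standard genetic code helpers shared by the sequence simulator and the
divergence estimators.

All sequences handled here are uppercase DNA over {A, C, G, T}; masked
positions (N) must be removed by codon masking before any function in this
module sees them.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Data import CodonTable

BASES = "ACGT"

_table = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, with '*' for stop codons
CODON_TO_AA: dict[str, str] = dict(_table.forward_table)
for _stop in _table.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS = frozenset(_table.stop_codons)
SENSE_CODONS = tuple(sorted(c for c in CODON_TO_AA if c not in STOP_CODONS))

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a codon; '*' for a stop."""
    try:
        return CODON_TO_AA[codon]
    except KeyError:
        raise ValueError(f"not an unambiguous DNA codon: {codon!r}") from None


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def is_transition(a: str, b: str) -> bool:
    """True for A<->G or C<->T substitutions."""
    return (a in _PURINES and b in _PURINES) or (
        a in _PYRIMIDINES and b in _PYRIMIDINES
    )


@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """Synonymous and non-synonymous site counts of one codon.

    For each of the three positions, every single-base change is classified
    as synonymous or non-synonymous against the standard code; changes that
    would create a stop codon are excluded and the position's one site is
    split between the remaining changes (so the two counts always sum to 3).

    Returns
    -------
    (s, n) : tuple of float
        Synonymous and non-synonymous site counts, s + n == 3.
    """
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValueError(f"codon must be 3 bases over ACGT, got {codon!r}")
    if is_stop(codon):
        raise ValueError(f"stop codon {codon!r} has no site decomposition")
    aa = CODON_TO_AA[codon]
    s_total = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if is_stop(mutant):
                continue
            valid += 1
            if CODON_TO_AA[mutant] == aa:
                syn += 1
        if valid:
            s_total += syn / valid
        # a position whose every neighbour is a stop contributes one
        # non-synonymous site by convention (cannot occur with the
        # standard code, but keeps the partition exact)
    return s_total, 3.0 - s_total
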