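"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with homeokit internals: translation goes
through Bio.Seq, tail probabilities through exact integer arithmetic, and
mismatch counts through character-by-character comparison.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

from Bio.Seq import Seq

STOPS = {"TAA", "TAG", "TGA"}


def hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


def translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())  # '*' for stops


# ---------------------------------------------------------------------------
# NG86 enumeration oracle

def ng86_sites(codon: str) -> float:
    """Synonymous site count of one codon; changes to stops are nonsynonymous."""
    aa = translate_codon(codon)
    syn = 0
    for i in range(3):
        for b in "ACGT":
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1 :]
            if alt not in STOPS and translate_codon(alt) == aa:
                syn += 1
    return syn / 3.0


def ng86_codon_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Average (syn, nonsyn) steps over substitution orderings between codons,
    skipping orderings that pass through a stop codon (using all orderings if
    every one does)."""
    diff_positions = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_positions:
        return 0.0, 0.0
    clean, dirty = [], []
    for order in itertools.permutations(diff_positions):
        cur, sd, nd, through_stop = c1, 0, 0, False
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            if nxt in STOPS:
                through_stop = True
            if (cur not in STOPS and nxt not in STOPS
                    and translate_codon(cur) == translate_codon(nxt)):
                sd += 1
            else:
                nd += 1
            cur = nxt
        (dirty if through_stop else clean).append((sd, nd))
    use = clean or dirty
    return (sum(x[0] for x in use) / len(use), sum(x[1] for x in use) / len(use))


def ng86_pair_counts(seq1: str, seq2: str) -> tuple[float, float, float, float]:
    """(S, N, Sd, Nd) over unmasked codons (no N, no stop in either)."""
    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if "N" in c1 or "N" in c2 or c1 in STOPS or c2 in STOPS:
            continue
        s = (ng86_sites(c1) + ng86_sites(c2)) / 2.0
        S += s
        N += 3.0 - s
        sd, nd = ng86_codon_diffs(c1, c2)
        Sd += sd
        Nd += nd
    return S, N, Sd, Nd


# ---------------------------------------------------------------------------
# Hypergeometric upper tail (exact)

def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact."""
    lo = max(0, K + n - N)
    hi = min(K, n)
    if k <= lo:
        return Fraction(1)
    total = sum(comb(K, x) * comb(N - K, n - x) for x in range(max(k, lo), hi + 1))
    return Fraction(total, comb(N, n))


# ---------------------------------------------------------------------------
# Benjamini-Hochberg via statsmodels (reference implementation)

def bh_reference(p_values):
    from statsmodels.stats.multitest import multipletests

    return multipletests(p_values, method="fdr_bh")[1]


def mutant_cds_translation(cds: str, offset: int, new_base: str) -> str:
    """Protein sequence of a CDS after substituting one base (full rebuild)."""
    mutated = cds[:offset] + new_base + cds[offset + 1 :]
    return str(Seq(mutated).translate())
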