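"""Ka/Ks estimation for homoeologous CDS pairs and Ks-based divergence dating.

Implements the Nei–Gojobori (1986) counting method with Jukes–Cantor
correction: synonymous site fractions from the standard genetic code averaged
over both sequences, pathway-averaged difference counts for codons with
multiple substitutions, and d = -(3/4)·ln(1 - 4p/3).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Optional

from Bio.Data import CodonTable

from .models import DivergenceEstimate, GeneModel, Genome, revcomp

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_TABLE.stop_codons)


def _aa(codon: str) -> Optional[str]:
    """Amino acid for a codon; None for stops."""
    return None if codon in _STOPS else _TABLE.forward_table[codon]


def _syn_site_fraction(codon: str) -> float:
    """Number of synonymous sites in one codon (0..3).

    Each position contributes the fraction of its three possible changes that
    preserve the amino acid; changes to stop codons count as nonsynonymous.
    """
    total = 0.0
    aa0 = _aa(codon)
    for i in range(3):
        syn = 0
        for b in "ACGT":
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1 :]
            if _aa(alt) is not None and _aa(alt) == aa0:
                syn += 1
        total += syn / 3.0
    return total


@dataclass(frozen=True)
class _PairCounts:
    s_sites: float
    n_sites: float
    s_diffs: float
    n_diffs: float
    n_codons: int


def _codon_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) difference counts.

    For codons differing at k positions, substitution orderings are
    enumerated; pathways passing through a stop codon are skipped (all
    pathways are used if every one hits a stop).
    """
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in itertools.permutations(positions):
        cur = c1
        sd = nd = 0
        hit_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                hit_stop = True
            if _aa(cur) is not None and _aa(nxt) is not None and _aa(cur) == _aa(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        (valid if not hit_stop else blocked).append((sd, nd))
    pathways = valid if valid else blocked
    s = sum(p[0] for p in pathways) / len(pathways)
    n = sum(p[1] for p in pathways) / len(pathways)
    return s, n


def count_sites_and_diffs(cds_a: str, cds_b: str) -> _PairCounts:
    """NG86 site and difference counts over the unmasked codons of a pair.

    Codons containing N or coding a stop in either sequence are masked.
    """
    if len(cds_a) != len(cds_b):
        raise ValueError("sequences differ in length")
    if len(cds_a) % 3:
        raise ValueError("length not a multiple of 3")
    s_sites = n_sites = s_diffs = n_diffs = 0.0
    n_codons = 0
    for i in range(0, len(cds_a), 3):
        c1, c2 = cds_a[i : i + 3], cds_b[i : i + 3]
        if "N" in c1 or "N" in c2:
            continue
        if c1 in _STOPS or c2 in _STOPS:
            if i + 3 < len(cds_a):  # terminal stop is expected; internal is not
                warnings.warn(f"internal stop codon at codon {i // 3}; masked")
            continue
        n_codons += 1
        s = (_syn_site_fraction(c1) + _syn_site_fraction(c2)) / 2.0
        s_sites += s
        n_sites += 3.0 - s
        sd, nd = _codon_diffs(c1, c2)
        s_diffs += sd
        n_diffs += nd
    return _PairCounts(s_sites, n_sites, s_diffs, n_diffs, n_codons)


def _jukes_cantor(p: float) -> Optional[float]:
    """JC69 multiple-hit correction; None when saturated (p >= 3/4)."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def ng86_ka_ks(cds_a: str, cds_b: str, gene: str = "") -> DivergenceEstimate:
    """NG86 Ka/Ks for one aligned, gap-free CDS pair."""
    counts = count_sites_and_diffs(cds_a, cds_b)
    ps = counts.s_diffs / counts.s_sites if counts.s_sites > 0 else 0.0
    pn = counts.n_diffs / counts.n_sites if counts.n_sites > 0 else 0.0
    ks = _jukes_cantor(ps)
    ka = _jukes_cantor(pn)
    omega = None
    if ka is not None and ks is not None and ks > 0:
        omega = ka / ks
    return DivergenceEstimate(
        gene=gene,
        n_sites=counts.n_sites,
        s_sites=counts.s_sites,
        n_diffs=counts.n_diffs,
        s_diffs=counts.s_diffs,
        ka=ka,
        ks=ks,
        omega=omega,
        saturated_ka=ka is None,
        saturated_ks=ks is None,
    )


# ---------------------------------------------------------------------------
# CDS extraction

def extract_cds_pair(
    gene: GeneModel, genome_a: Genome, genome_b: Genome
) -> tuple[str, str]:
    """Strand-aware spliced CDS from both genomes at shared coordinates.

    Codons containing N in either sequence are removed from both, keeping the
    pair aligned.
    """
    def splice(genome: Genome) -> str:
        seq = "".join(genome.fetch(gene.contig, s, e) for s, e in gene.cds)
        return seq if gene.strand == "+" else revcomp(seq)

    cds_a, cds_b = splice(genome_a), splice(genome_b)
    if len(cds_a) % 3:
        raise ValueError(f"{gene.gene_id}: CDS length {len(cds_a)} not a multiple of 3")
    keep_a = []
    keep_b = []
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3], cds_b[i : i + 3]
        if "N" in ca or "N" in cb:
            continue
        keep_a.append(ca)
        keep_b.append(cb)
    return "".join(keep_a), "".join(keep_b)


# ---------------------------------------------------------------------------
# Divergence time

@dataclass(frozen=True)
class DivergenceConfig:
    """Dating parameters; the default rate is 6.1e-9 substitutions/site/year."""

    rate: float = 6.1e-9
    method: str = "NG86"

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("substitution rate must be > 0")


def divergence_time(ks_values, config: DivergenceConfig = DivergenceConfig()) -> float:
    """T = mean(Ks) / (2 × rate); saturated/absent values are excluded."""
    usable = [k for k in ks_values if k is not None and math.isfinite(k)]
    if not usable:
        raise ValueError("no usable Ks values")
    return (sum(usable) / len(usable)) / (2.0 * config.rate)
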