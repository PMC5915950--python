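"""Homoeologous SNP identification and coding-effect annotation.

A position is a homoeologous SNP when the second ancestor's reads carry the
variant near-uniformly against the reference (homogenic call) while the
hybrid's reads carry both alleles (heterogenic call), with the same variant
base in both call sets.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd
from Bio.Data import CodonTable

from .models import (
    CallClass,
    CodingEffect,
    GeneModel,
    Genome,
    HomoeoSnp,
    Region,
    SnpCall,
    VariantEffect,
    revcomp,
)

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_CODON_TABLE.stop_codons)

SPLICE_SITE_WIDTH = 2  # bases of intron adjacent to an exon boundary


@dataclass(frozen=True)
class Thresholds:
    """Call-classification cutoffs.

    The depth floor follows the upstream caller's default; the frequency
    windows are configurable because the source analysis does not state them.
    """

    min_depth: int = 8
    homo_freq: float = 0.9
    het_low: float = 0.3
    het_high: float = 0.7

    def __post_init__(self) -> None:
        if not 0.5 < self.homo_freq <= 1.0:
            raise ValueError("homo_freq must be in (0.5, 1]")
        if not self.het_low < self.het_high < self.homo_freq:
            raise ValueError("require het_low < het_high < homo_freq")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")


DEFAULT_THRESHOLDS = Thresholds()


def classify_call(call: SnpCall, thresholds: Thresholds = DEFAULT_THRESHOLDS) -> CallClass:
    """Classify one call as HOMOGENIC, HETEROGENIC, or AMBIGUOUS."""
    if call.depth < thresholds.min_depth:
        return CallClass.AMBIGUOUS
    if call.var_freq >= thresholds.homo_freq:
        return CallClass.HOMOGENIC
    if thresholds.het_low <= call.var_freq <= thresholds.het_high:
        return CallClass.HETEROGENIC
    return CallClass.AMBIGUOUS


def _check_unique(calls: Iterable[SnpCall], label: str) -> None:
    seen = Counter((c.contig, c.pos) for c in calls)
    dupes = [k for k, n in seen.items() if n > 1]
    if dupes:
        contig, pos = dupes[0]
        raise ValueError(f"duplicate position in {label} calls: {contig}:{pos}")


def identify_homoeologous_snps(
    calls_b_vs_a: list[SnpCall],
    calls_h_vs_a: list[SnpCall],
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> list[HomoeoSnp]:
    """Intersect homogenic ancestor-B calls with heterogenic hybrid calls.

    Returns the positions where both call sets agree on contig, position, and
    variant base, sorted by (contig, pos).
    """
    _check_unique(calls_b_vs_a, "B-vs-A")
    _check_unique(calls_h_vs_a, "hybrid-vs-A")
    het = {
        (c.contig, c.pos): c
        for c in calls_h_vs_a
        if classify_call(c, thresholds) is CallClass.HETEROGENIC
    }
    out = []
    for c in calls_b_vs_a:
        if classify_call(c, thresholds) is not CallClass.HOMOGENIC:
            continue
        partner = het.get((c.contig, c.pos))
        if partner is None or partner.var_base != c.var_base:
            continue
        out.append(HomoeoSnp(c.contig, c.pos, c.ref_base, c.var_base))
    return sorted(out)


# ---------------------------------------------------------------------------
# Effect annotation

def _spliced_cds(gene: GeneModel, genome: Genome) -> str:
    chunks = [genome.fetch(gene.contig, s, e) for s, e in gene.cds]
    seq = "".join(chunks)
    return seq if gene.strand == "+" else revcomp(seq)


def _cds_offset(gene: GeneModel, pos: int) -> Optional[int]:
    """0-based offset of a genomic position within the spliced CDS, or None."""
    acc = 0
    if gene.strand == "+":
        for s, e in gene.cds:
            if s <= pos <= e:
                return acc + (pos - s)
            acc += e - s + 1
    else:
        for s, e in reversed(gene.cds):
            if s <= pos <= e:
                return acc + (e - pos)
            acc += e - s + 1
    return None


def annotate_effect(
    snp: HomoeoSnp, gene_models: list[GeneModel], genome_a: Genome
) -> VariantEffect:
    """Locate a SNP in the gene structure and predict its coding effect.

    Splice sites are the first ``SPLICE_SITE_WIDTH`` intronic bases on either
    side of an exon boundary and take precedence over INTRON. Coding effects
    come from substituting the alternate allele into its codon (strand-aware)
    and translating with the standard genetic code.
    """
    if genome_a.base_at(snp.contig, snp.pos) != snp.allele_ref:
        raise ValueError(
            f"reference mismatch at {snp.contig}:{snp.pos}: map says {snp.allele_ref}, "
            f"genome has {genome_a.base_at(snp.contig, snp.pos)}"
        )
    gene = next(
        (g for g in gene_models if g.contig == snp.contig and g.start <= snp.pos <= g.end),
        None,
    )
    if gene is None:
        return VariantEffect(snp, Region.INTERGENIC, CodingEffect.NONE)

    pos = snp.pos
    in_cds = any(s <= pos <= e for s, e in gene.cds)
    if in_cds:
        return VariantEffect(
            snp, Region.EXON_CDS, _coding_effect(snp, gene, genome_a), gene.gene_id
        )
    if any(s <= pos <= e for s, e in gene.exons):
        return VariantEffect(snp, Region.UTR, CodingEffect.NONE, gene.gene_id)
    for s, e in gene.introns():
        if s <= pos <= e:
            if pos - s < SPLICE_SITE_WIDTH or e - pos < SPLICE_SITE_WIDTH:
                return VariantEffect(snp, Region.SPLICE_SITE, CodingEffect.NONE, gene.gene_id)
            return VariantEffect(snp, Region.INTRON, CodingEffect.NONE, gene.gene_id)
    # inside the gene span but outside exons and introns cannot happen with
    # contiguous exon models; fall back to UTR-less intergenic
    return VariantEffect(snp, Region.INTERGENIC, CodingEffect.NONE)


def _coding_effect(snp: HomoeoSnp, gene: GeneModel, genome: Genome) -> CodingEffect:
    cds = _spliced_cds(gene, genome)
    offset = _cds_offset(gene, snp.pos)
    assert offset is not None
    codon_idx, codon_pos = divmod(offset, 3)
    codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
    alt = snp.allele_alt if gene.strand == "+" else revcomp(snp.allele_alt)
    mutant = codon[:codon_pos] + alt + codon[codon_pos + 1 :]
    n_codons = len(cds) // 3
    if codon_idx == 0 and codon == "ATG" and mutant != "ATG":
        return CodingEffect.START_LOST
    if codon in _STOPS:
        return CodingEffect.STOP_LOST if mutant not in _STOPS else CodingEffect.SYNONYMOUS
    if mutant in _STOPS:
        return CodingEffect.STOP_GAINED
    aa_ref = _CODON_TABLE.forward_table[codon]
    aa_alt = _CODON_TABLE.forward_table[mutant]
    return CodingEffect.SYNONYMOUS if aa_ref == aa_alt else CodingEffect.NONSYNONYMOUS


def summarize_effects(effects: list[VariantEffect]) -> dict:
    """Tally effects by region and coding effect; flag genes with impact."""
    by_region = Counter(e.region.value for e in effects)
    by_effect = Counter(e.coding_effect.value for e in effects)
    flagged = (
        CodingEffect.NONSYNONYMOUS,
        CodingEffect.START_LOST,
        CodingEffect.STOP_GAINED,
        CodingEffect.STOP_LOST,
    )
    gene_flags: dict[str, dict[str, bool]] = {}
    for e in effects:
        if e.gene_id is None:
            continue
        flags = gene_flags.setdefault(
            e.gene_id, {f.value: False for f in flagged}
        )
        if e.coding_effect in flagged:
            flags[e.coding_effect.value] = True
    return {
        "by_region": {r.value: by_region.get(r.value, 0) for r in Region},
        "by_coding_effect": {c.value: by_effect.get(c.value, 0) for c in CodingEffect},
        "gene_flags": gene_flags,
        "n_total": len(effects),
    }


def effects_to_frame(effects: list[VariantEffect]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (e.snp.contig, e.snp.pos, e.snp.allele_ref, e.snp.allele_alt,
             e.region.value, e.coding_effect.value, e.gene_id or "")
            for e in effects
        ],
        columns=["contig", "pos", "allele_ref", "allele_alt", "region", "coding_effect", "gene_id"],
    )
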