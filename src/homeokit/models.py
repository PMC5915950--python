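"""Core domain types shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class CallClass(str, Enum):
    """Classification of a single SNP call by depth and variant frequency."""

    HOMOGENIC = "HOMOGENIC"
    HETEROGENIC = "HETEROGENIC"
    AMBIGUOUS = "AMBIGUOUS"


class Region(str, Enum):
    INTERGENIC = "INTERGENIC"
    INTRON = "INTRON"
    EXON_CDS = "EXON_CDS"
    UTR = "UTR"
    SPLICE_SITE = "SPLICE_SITE"


class CodingEffect(str, Enum):
    NONE = "NONE"
    SYNONYMOUS = "SYNONYMOUS"
    NONSYNONYMOUS = "NONSYNONYMOUS"
    START_LOST = "START_LOST"
    STOP_GAINED = "STOP_GAINED"
    STOP_LOST = "STOP_LOST"


class Origin(str, Enum):
    ORIGIN_A = "ORIGIN_A"
    ORIGIN_B = "ORIGIN_B"
    UNCLASSIFIED = "UNCLASSIFIED"


class Relation(str, Enum):
    """Significance relation between two expression groups, first-vs-second."""

    EQ = "EQ"
    GT = "GT"
    LT = "LT"


class AdditivityCategory(str, Enum):
    ADDITIVE = "ADDITIVE"
    ELD_BD = "ELD_BD"
    ELD_BS = "ELD_BS"
    TRANSGRESSIVE_UP = "TRANSGRESSIVE_UP"
    TRANSGRESSIVE_DOWN = "TRANSGRESSIVE_DOWN"
    OTHER_NONADDITIVE = "OTHER_NONADDITIVE"


class BiasCategory(str, Enum):
    NO_BIAS = "NO_BIAS"
    BIAS_RETAINED = "BIAS_RETAINED"
    BIAS_LOST = "BIAS_LOST"
    BIAS_GAINED = "BIAS_GAINED"
    BIAS_REVERSED = "BIAS_REVERSED"


class PatternClass(str, Enum):
    ANCESTRAL = "ANCESTRAL"
    NONANCESTRAL = "NONANCESTRAL"


BASES = "ACGT"


class Genome:
    """An ordered collection of named nucleotide sequences.

    Sequences are plain upper-case strings over A/C/G/T/N. Positions at the
    public API are 1-based; internal slicing is 0-based.
    """

    def __init__(self, contigs: dict[str, str]):
        if not contigs:
            raise ValueError("genome must have at least one contig")
        for name, seq in contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
        self.contigs: dict[str, str] = dict(contigs)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Genome) and self.contigs == other.contigs

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def __getitem__(self, contig: str) -> str:
        return self.contigs[contig]

    def base_at(self, contig: str, pos: int) -> str:
        """Return the base at a 1-based position."""
        return self.contigs[contig][pos - 1]

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Return the sequence of the 1-based inclusive interval [start, end]."""
        return self.contigs[contig][start - 1 : end]

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}


@dataclass(frozen=True)
class GeneModel:
    """A gene with exon and CDS intervals, 1-based inclusive, genome order."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str  # '+' or '-'
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if not self.exons:
            raise ValueError(f"{self.gene_id} has no exons")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out


@dataclass(frozen=True)
class SnpCall:
    """One pileup-style SNP call against the reference genome."""

    contig: str
    pos: int  # 1-based
    ref_base: str
    var_base: str
    depth: int
    var_freq: float

    def __post_init__(self) -> None:
        if self.var_base == self.ref_base:
            raise ValueError(f"var == ref at {self.contig}:{self.pos}")
        if not 0.0 <= self.var_freq <= 1.0:
            raise ValueError(f"var_freq out of [0,1] at {self.contig}:{self.pos}")
        if self.depth < 0:
            raise ValueError(f"negative depth at {self.contig}:{self.pos}")


@dataclass(frozen=True, order=True)
class HomoeoSnp:
    """A reference position carrying different alleles in the two ancestors."""

    contig: str
    pos: int  # 1-based
    allele_ref: str
    allele_alt: str

    def __post_init__(self) -> None:
        if self.allele_alt == self.allele_ref:
            raise ValueError(f"alleles identical at {self.contig}:{self.pos}")


@dataclass(frozen=True)
class VariantEffect:
    snp: HomoeoSnp
    region: Region
    coding_effect: CodingEffect
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.coding_effect is not CodingEffect.NONE and self.region is not Region.EXON_CDS:
            raise ValueError("coding effect outside CDS")


@dataclass(frozen=True)
class ReadAlignment:
    """One read alignment against a single genome; nm is the edit distance."""

    read_id: str
    contig: Optional[str]
    pos: Optional[int]  # 1-based leftmost
    mapped: bool
    nm: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mapped:
            if self.nm is None or self.nm < 0:
                raise ValueError(f"mapped read {self.read_id} needs nm >= 0")
        elif self.nm is not None:
            raise ValueError(f"unmapped read {self.read_id} must not carry nm")


@dataclass(frozen=True)
class SortedRead:
    read_id: str
    origin: Origin
    nm_a: Optional[int] = None
    nm_b: Optional[int] = None


@dataclass(frozen=True)
class DivergenceEstimate:
    """Per homoeolog pair: substitution-rate estimates and counted sites."""

    gene: str
    n_sites: float
    s_sites: float
    n_diffs: float
    s_diffs: float
    ka: Optional[float]
    ks: Optional[float]
    omega: Optional[float]
    saturated_ka: bool = False
    saturated_ks: bool = False
    t_years: Optional[float] = None


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
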