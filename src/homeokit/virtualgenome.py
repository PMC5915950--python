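"""Virtual second-ancestor genome: allele substitution into the reference."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .models import Genome, HomoeoSnp

logger = logging.getLogger(__name__)


class ReferenceMismatchError(ValueError):
    pass


def build_virtual_genome(
    genome: Genome, snps: list[HomoeoSnp], strict: bool = True
) -> Genome:
    """Substitute each SNP's alternate allele into the reference genome.

    In strict mode (default) a SNP whose reference allele disagrees with the
    genome raises; in lenient mode it is skipped with a log message. Contig
    order, names, and lengths are preserved.
    """
    arrays = {name: bytearray(seq.encode()) for name, seq in genome.contigs.items()}
    for snp in snps:
        if snp.contig not in arrays:
            raise KeyError(f"unknown contig {snp.contig!r}")
        arr = arrays[snp.contig]
        if not 1 <= snp.pos <= len(arr):
            raise IndexError(f"position {snp.contig}:{snp.pos} outside contig")
        current = chr(arr[snp.pos - 1])
        if current != snp.allele_ref:
            msg = (
                f"reference mismatch at {snp.contig}:{snp.pos}: "
                f"map says {snp.allele_ref}, genome has {current}"
            )
            if strict:
                raise ReferenceMismatchError(msg)
            logger.warning("%s — skipped", msg)
            continue
        arr[snp.pos - 1] = ord(snp.allele_alt)
    return Genome({name: arr.decode() for name, arr in arrays.items()})


def swap_alleles(snps: list[HomoeoSnp]) -> list[HomoeoSnp]:
    """Invert a map so reapplying it to the virtual genome restores the original."""
    return [HomoeoSnp(s.contig, s.pos, s.allele_alt, s.allele_ref) for s in snps]


@dataclass
class SubstitutionReport:
    n_expected: int
    n_applied: int
    mismatches: list[tuple[str, int, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.n_applied == self.n_expected and not self.mismatches


def verify_substitutions(
    original: Genome, virtual: Genome, snps: list[HomoeoSnp]
) -> SubstitutionReport:
    """Independently check a virtual genome against its SNP map.

    n_applied counts map positions where the virtual genome carries the
    alternate allele. mismatches lists map positions lacking the alternate
    allele and any position differing between the genomes outside the map.
    """
    if set(original.contigs) != set(virtual.contigs):
        raise ValueError("contig sets differ between original and virtual genome")
    mapped = {(s.contig, s.pos): s for s in snps}
    n_applied = 0
    mismatches: list[tuple[str, int, str]] = []
    for (contig, pos), snp in mapped.items():
        if virtual.base_at(contig, pos) == snp.allele_alt:
            n_applied += 1
        else:
            mismatches.append((contig, pos, "allele_alt absent in virtual genome"))
    for contig, seq in original.contigs.items():
        vseq = virtual.contigs[contig]
        if len(seq) != len(vseq):
            mismatches.append((contig, 0, "contig length changed"))
            continue
        for i, (a, b) in enumerate(zip(seq, vseq)):
            if a != b and (contig, i + 1) not in mapped:
                mismatches.append((contig, i + 1, "difference outside the SNP map"))
    return SubstitutionReport(len(mapped), n_applied, mismatches)
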