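"""Subgenome-of-origin read sorting by mismatch-count comparison.

Each hybrid read is aligned to both ancestral genomes; the genome with the
fewer mismatches claims the read, ties and double-unmapped reads stay
unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .models import Origin, ReadAlignment, SortedRead


def sort_read(nm_a: Optional[int], nm_b: Optional[int]) -> Origin:
    """Assign origin from the two mismatch counts (None = unmapped)."""
    for nm in (nm_a, nm_b):
        if nm is not None and nm < 0:
            raise ValueError("negative mismatch count")
    if nm_a is None and nm_b is None:
        return Origin.UNCLASSIFIED
    if nm_b is None:
        return Origin.ORIGIN_A
    if nm_a is None:
        return Origin.ORIGIN_B
    if nm_a < nm_b:
        return Origin.ORIGIN_A
    if nm_b < nm_a:
        return Origin.ORIGIN_B
    return Origin.UNCLASSIFIED


@dataclass
class SortSummary:
    n_total: int
    fraction_a: float
    fraction_b: float
    fraction_unclassified: float

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "fraction_a": self.fraction_a,
            "fraction_b": self.fraction_b,
            "fraction_unclassified": self.fraction_unclassified,
        }


def _reduce_primary(alignments: list[ReadAlignment]) -> dict[str, Optional[ReadAlignment]]:
    """Keep one alignment per read: the lowest-nm mapped one.

    A tie between distinct mapped alignments of the same read is unresolvable
    evidence; the read's entry becomes None (forced UNCLASSIFIED downstream).
    """
    groups: dict[str, list[ReadAlignment]] = {}
    for aln in alignments:
        groups.setdefault(aln.read_id, []).append(aln)
    best: dict[str, Optional[ReadAlignment]] = {}
    for rid, alns in groups.items():
        mapped = [a for a in alns if a.mapped]
        if not mapped:
            best[rid] = None
            continue
        min_nm = min(a.nm for a in mapped)  # type: ignore[type-var]
        top = [a for a in mapped if a.nm == min_nm]
        distinct = {(a.contig, a.pos) for a in top}
        best[rid] = top[0] if len(distinct) == 1 else None
    return best


def sort_reads(
    alignments_a: list[ReadAlignment],
    alignments_b: list[ReadAlignment],
    max_nm: Optional[int] = None,
) -> tuple[list[SortedRead], SortSummary]:
    """Sort every read seen in either alignment set; one output row per read.

    ``max_nm``, when set, drops alignments with more mismatches before the
    comparison (defaults off).
    """
    best_a = _reduce_primary(alignments_a)
    best_b = _reduce_primary(alignments_b)
    read_ids = sorted(set(best_a) | set(best_b))
    out: list[SortedRead] = []
    tally = {Origin.ORIGIN_A: 0, Origin.ORIGIN_B: 0, Origin.UNCLASSIFIED: 0}
    for rid in read_ids:
        aln_a = best_a.get(rid)
        aln_b = best_b.get(rid)
        nm_a = aln_a.nm if aln_a is not None and aln_a.mapped else None
        nm_b = aln_b.nm if aln_b is not None and aln_b.mapped else None
        if max_nm is not None:
            if nm_a is not None and nm_a > max_nm:
                nm_a = None
            if nm_b is not None and nm_b > max_nm:
                nm_b = None
        origin = sort_read(nm_a, nm_b)
        tally[origin] += 1
        out.append(SortedRead(rid, origin, nm_a, nm_b))
    n = len(out)
    summary = SortSummary(
        n_total=n,
        fraction_a=tally[Origin.ORIGIN_A] / n if n else 0.0,
        fraction_b=tally[Origin.ORIGIN_B] / n if n else 0.0,
        fraction_unclassified=tally[Origin.UNCLASSIFIED] / n if n else 0.0,
    )
    return out, summary


def sorted_reads_to_frame(reads: list[SortedRead]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.read_id,
             "" if r.nm_a is None else r.nm_a,
             "" if r.nm_b is None else r.nm_b,
             r.origin.value)
            for r in reads
        ],
        columns=["read_id", "nm_a", "nm_b", "origin"],
    )
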