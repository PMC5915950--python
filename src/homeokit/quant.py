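"""Read counting, RPM, expressed-gene filter, mid-ancestral pseudo-samples,
and sample correlation matrices."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .models import GeneModel


@dataclass
class CountSet:
    """Gene × sample counts with sample metadata and library sizes.

    ``samples`` is indexed by sample id with columns group / condition /
    replicate; ``library_sizes`` shares that index.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("counts columns and sample metadata disagree")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        for grp, sub in self.samples.groupby(["group", "condition"]):
            reps = sub["replicate"].tolist()
            if len(reps) != len(set(reps)):
                raise ValueError(f"duplicate replicate index in group {grp}")

    def subset(self, group: str, condition: Optional[str] = None) -> "CountSet":
        mask = self.samples["group"] == group
        if condition is not None:
            mask &= self.samples["condition"] == condition
        ids = self.samples.index[mask]
        return CountSet(self.counts[ids], self.samples.loc[ids], self.library_sizes[ids])


# ---------------------------------------------------------------------------
# Counting

def _exon_index(gene_models: list[GeneModel]) -> dict[str, list[tuple[int, int, str]]]:
    idx: dict[str, list[tuple[int, int, str]]] = {}
    for g in gene_models:
        for s, e in g.exons:
            idx.setdefault(g.contig, []).append((s, e, g.gene_id))
    for contig in idx:
        idx[contig].sort()
    return idx


def count_reads(
    read_loci: Iterable[tuple[str, str, int, int]],
    gene_models: list[GeneModel],
) -> tuple[pd.Series, dict]:
    """Count reads per gene by exon-union overlap.

    ``read_loci`` yields (read_id, contig, start, end) in 1-based inclusive
    reference coordinates. A read is assigned to a gene iff its interval
    overlaps the exon union of exactly one gene; overlaps with zero genes are
    unassigned, with two or more genes ambiguous. Returns (per-gene counts,
    summary with assigned/ambiguous/unassigned tallies).
    """
    index = _exon_index(gene_models)
    known_contigs = {g.contig for g in gene_models}
    counts = pd.Series(0, index=pd.Index([g.gene_id for g in gene_models], name="gene"))
    assigned = ambiguous = unassigned = total = 0
    for read_id, contig, start, end in read_loci:
        total += 1
        if contig not in known_contigs:
            raise KeyError(f"read {read_id}: unknown contig {contig!r}")
        hits = {
            gid
            for s, e, gid in index.get(contig, [])
            if s <= end and start <= e
        }
        if len(hits) == 1:
            counts[next(iter(hits))] += 1
            assigned += 1
        elif len(hits) == 0:
            unassigned += 1
        else:
            ambiguous += 1
    return counts, {
        "total": total,
        "assigned": assigned,
        "ambiguous": ambiguous,
        "unassigned": unassigned,
    }


# ---------------------------------------------------------------------------
# RPM and the expressed filter

def compute_rpm(counts: pd.DataFrame, library_sizes: pd.Series) -> pd.DataFrame:
    """Reads per million mapped reads: 10^6 × count / library size."""
    if (library_sizes <= 0).any():
        bad = library_sizes.index[library_sizes <= 0].tolist()
        raise ValueError(f"non-positive library size for samples: {bad}")
    return counts.div(library_sizes, axis=1) * 1e6


def flag_expressed(rpm_values: Iterable[float], threshold: float = 1.0) -> bool:
    """True iff every replicate's RPM meets the threshold (inclusive)."""
    values = list(rpm_values)
    if not values:
        raise ValueError("empty replicate list")
    return all(v >= threshold for v in values)


# ---------------------------------------------------------------------------
# MAV / group-sum pseudo-samples

def sum_replicate_groups(
    counts_1: pd.DataFrame,
    counts_2: pd.DataFrame,
    lib_1: pd.Series,
    lib_2: pd.Series,
    name: str,
) -> tuple[pd.DataFrame, pd.Series]:
    """Sum two groups' count columns pairwise by replicate order.

    This single code path builds both the mid-ancestral pseudo-samples
    (ancestor1 + ancestor2) and the hybrid totals (subgenome1 + subgenome2):
    replicate r of the output has the summed counts and the summed library
    sizes, so its RPM is the library-size-weighted mean of the inputs' RPMs.
    Columns are paired positionally (replicate order).
    """
    if counts_1.shape[1] != counts_2.shape[1]:
        raise ValueError(
            f"unequal replicate counts: {counts_1.shape[1]} vs {counts_2.shape[1]}"
        )
    out_cols = {}
    out_libs = {}
    for r, (c1, c2) in enumerate(zip(counts_1.columns, counts_2.columns), start=1):
        col = f"{name}_r{r}"
        out_cols[col] = counts_1[c1].values + counts_2[c2].values
        out_libs[col] = lib_1[c1] + lib_2[c2]
    counts = pd.DataFrame(out_cols, index=counts_1.index)
    return counts, pd.Series(out_libs)


def compute_mav(
    counts_bd: pd.DataFrame,
    counts_bs: pd.DataFrame,
    lib_bd: pd.Series,
    lib_bs: pd.Series,
) -> tuple[pd.DataFrame, pd.Series]:
    """Mid-ancestral pseudo-samples: summed ancestor counts and library sizes."""
    return sum_replicate_groups(counts_bd, counts_bs, lib_bd, lib_bs, "MAV")


# ---------------------------------------------------------------------------
# Correlations

def pcc_matrix(rpm: pd.DataFrame, samples: Optional[list[str]] = None,
               log_transform: bool = True) -> pd.DataFrame:
    """Pearson correlation between sample expression profiles.

    Computed on log2(RPM + 1) by default. Samples with a constant profile get
    NaN correlations (flagged with a warning), never a silent 0.
    """
    data = rpm if samples is None else rpm[samples]
    if data.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    mat = np.log2(data.values + 1.0) if log_transform else data.values.astype(float)
    constant = mat.std(axis=0) == 0
    if constant.any():
        bad = list(data.columns[constant])
        warnings.warn(f"constant expression profile, correlations undefined: {bad}")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat, rowvar=False)
    corr[constant, :] = np.nan
    corr[:, constant] = np.nan
    np.fill_diagonal(corr, np.where(constant, np.nan, 1.0))
    return pd.DataFrame(corr, index=data.columns, columns=data.columns)
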