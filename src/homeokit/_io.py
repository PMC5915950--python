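"""Readers/writers for the plain-text formats exchanged between stages.

FASTA goes through Biopython, SAM through pysam, VCF through pysam's
VariantFile, tables through pandas. GFF3 is written directly (the emitted
subset is gene/exon/CDS only) and read back with gffutils.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import Genome, GeneModel, HomoeoSnp, ReadAlignment, SnpCall

SNP_CALL_COLUMNS = ["contig", "pos", "ref", "var", "depth", "var_freq"]
HOMOEOSNP_COLUMNS = ["contig", "pos", "allele_ref", "allele_alt"]


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(genome: Genome, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.contigs.items()
    ]
    SeqIO.write(records, str(path), "fasta")  # wraps at 60 columns


def read_fasta(path: str | Path) -> Genome:
    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    return Genome(contigs)


# ---------------------------------------------------------------------------
# GFF3

def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.contig}\thomeokit\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mrna_id = f"{g.gene_id}.1"
            fh.write(
                f"{g.contig}\thomeokit\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.contig}\thomeokit\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna_id}.exon{i};Parent={mrna_id}\n"
                )
            # CDS phase: cumulative length determines frame of each chunk
            chunks = list(g.cds) if g.strand == "+" else list(reversed(g.cds))
            consumed = 0
            phases = {}
            for s, e in chunks:
                phases[(s, e)] = (3 - consumed % 3) % 3
                consumed += e - s + 1
            for i, (s, e) in enumerate(g.cds, 1):
                fh.write(
                    f"{g.contig}\thomeokit\tCDS\t{s}\t{e}\t.\t{g.strand}\t{phases[(s, e)]}\t"
                    f"ID={mrna_id}.cds{i};Parent={mrna_id}\n"
                )


def read_gff3(path: str | Path) -> list[GeneModel]:
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = []
        cds = []
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = [(f.start, f.end) for f in db.children(mrna, featuretype="exon", order_by="start")]
            cds = [(f.start, f.end) for f in db.children(mrna, featuretype="CDS", order_by="start")]
            break  # one transcript per gene in this artifact
        genes.append(
            GeneModel(
                gene_id=gene.id,
                contig=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand,
                exons=tuple(exons),
                cds=tuple(cds),
            )
        )
    return genes


# ---------------------------------------------------------------------------
# SNP call tables

def write_snp_calls(calls: Iterable[SnpCall], path: str | Path) -> None:
    df = pd.DataFrame(
        [(c.contig, c.pos, c.ref_base, c.var_base, c.depth, c.var_freq) for c in calls],
        columns=SNP_CALL_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_snp_calls(path: str | Path) -> list[SnpCall]:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    missing = set(SNP_CALL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"SNP call table {path} missing columns: {sorted(missing)}")
    return [
        SnpCall(
            contig=row.contig,
            pos=int(row.pos),
            ref_base=row.ref,
            var_base=row.var,
            depth=int(row.depth),
            var_freq=float(row.var_freq),
        )
        for row in df.itertuples()
    ]


def read_snp_calls_vcf(path: str | Path, sample: Optional[str] = None) -> list[SnpCall]:
    """Read bi-allelic SNVs from a VCF v4 file into SnpCall records.

    depth comes from FORMAT/DP (fallback INFO/DP); var_freq from FORMAT/AD
    (alt / total) or INFO/AF. Records without usable depth/frequency are
    skipped.
    """
    calls = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_names = list(vcf.header.samples)
        use_sample = sample if sample is not None else (sample_names[0] if sample_names else None)
        for rec in vcf:
            if len(rec.alleles) != 2:
                continue
            ref, alt = rec.alleles
            if len(ref) != 1 or len(alt) != 1 or ref == alt:
                continue
            depth = None
            freq = None
            if use_sample is not None:
                fmt = rec.samples[use_sample]
                if "DP" in fmt and fmt["DP"] is not None:
                    depth = int(fmt["DP"])
                ad = fmt.get("AD")
                if ad is not None and len(ad) == 2 and ad[0] is not None:
                    total = ad[0] + ad[1]
                    if depth is None:
                        depth = int(total)
                    if total > 0:
                        freq = ad[1] / total
            if depth is None and "DP" in rec.info:
                depth = int(rec.info["DP"])
            if freq is None and "AF" in rec.info:
                af = rec.info["AF"]
                freq = float(af[0] if isinstance(af, tuple) else af)
            if depth is None or freq is None:
                continue
            calls.append(
                SnpCall(
                    contig=rec.chrom,
                    pos=rec.pos,
                    ref_base=ref,
                    var_base=alt,
                    depth=depth,
                    var_freq=freq,
                )
            )
    return calls


def write_homoeosnps(snps: Iterable[HomoeoSnp], path: str | Path) -> None:
    df = pd.DataFrame(
        [(s.contig, s.pos, s.allele_ref, s.allele_alt) for s in snps],
        columns=HOMOEOSNP_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_homoeosnps(path: str | Path) -> list[HomoeoSnp]:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    return [
        HomoeoSnp(row.contig, int(row.pos), row.allele_ref, row.allele_alt)
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# SAM

def write_sam(
    alignments: Iterable[tuple[ReadAlignment, str]],
    genome_lengths: dict[str, int],
    path: str | Path,
) -> None:
    """Write (alignment, read sequence) pairs as a minimal SAM file with NM tags."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name, length in genome_lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for aln, seq in alignments:
            if aln.mapped:
                cigar = f"{len(seq)}M"
                fh.write(
                    f"{aln.read_id}\t0\t{aln.contig}\t{aln.pos}\t60\t{cigar}\t*\t0\t0\t"
                    f"{seq}\t*\tNM:i:{aln.nm}\n"
                )
            else:
                fh.write(f"{aln.read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*\n")


def read_sam(path: str | Path) -> list[ReadAlignment]:
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                out.append(ReadAlignment(rec.query_name, None, None, mapped=False))
            else:
                if not rec.has_tag("NM"):
                    raise ValueError(f"alignment of {rec.query_name} lacks NM tag")
                out.append(
                    ReadAlignment(
                        rec.query_name,
                        rec.reference_name,
                        rec.reference_start + 1,
                        mapped=True,
                        nm=int(rec.get_tag("NM")),
                    )
                )
    return out


# ---------------------------------------------------------------------------
# Count matrices

def write_counts(counts: pd.DataFrame, samples: pd.DataFrame, library_sizes: pd.Series,
                 counts_path: str | Path, meta_path: str | Path) -> None:
    counts.to_csv(counts_path, sep="\t", index_label="gene")
    meta = samples.copy()
    meta["library_size"] = library_sizes
    meta.to_csv(meta_path, sep="\t", index_label="sample")


def read_counts(counts_path: str | Path, meta_path: str | Path):
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene")
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample")
    library_sizes = meta.pop("library_size")
    return counts, meta, library_sizes


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
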