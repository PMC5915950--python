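"""Truth-labelled synthetic allopolyploid study generator.

Produces a diverged ancestral genome pair, gene models, SNP call tables
(homozygous-like for ancestor B, ~50% frequency for the hybrid), reads of
known subgenome origin, oracle alignments against both genomes, and
negative-binomial count matrices with planted additivity and homoeolog-bias
categories. Every random draw flows from ``SimConfig.seed`` via named
substreams so identical configs reproduce byte-identical outputs.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .models import (
    AdditivityCategory,
    BiasCategory,
    Genome,
    GeneModel,
    HomoeoSnp,
    ReadAlignment,
    SnpCall,
    revcomp,
)

BASES = np.frombuffer(b"ACGT", dtype="S1")
STOP_CODONS = ("TAA", "TAG", "TGA")

GROUPS = ("BD", "BS", "BH_BD", "BH_BS")

DEFAULT_CATEGORY_PROPORTIONS = {
    "ADDITIVE": 0.60,
    "ELD_BD": 0.10,
    "ELD_BS": 0.10,
    "TRANSGRESSIVE_UP": 0.10,
    "TRANSGRESSIVE_DOWN": 0.10,
}

DEFAULT_BIAS_PROPORTIONS = {
    "NO_BIAS": 0.40,
    "BIAS_RETAINED": 0.15,
    "BIAS_LOST": 0.15,
    "BIAS_GAINED": 0.15,
    "BIAS_REVERSED": 0.15,
}

# ELD planting makes the ancestors differ by the fold factor, so the planted
# bias category must also have unequal ancestral expression.
_BIASED_ANCESTOR_CATEGORIES = ("BIAS_RETAINED", "BIAS_LOST", "BIAS_REVERSED")


@dataclass
class SimConfig:
    seed: int = 0
    genome_length: int = 100_000
    n_contigs: int = 1
    n_genes: int = 50
    divergence_rate: float = 0.005
    read_length: int = 150
    n_reads: int = 10_000
    error_rate: float = 0.002
    n_replicates: int = 3
    library_size: int = 1_000_000
    mu_log: float = math.log(1e-4)
    sigma_log: float = 0.5
    baseline_floor: float = 0.0  # lower clip for baseline fractions
    dispersion: float = 0.05
    fold_change: float = 4.0
    category_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PROPORTIONS)
    )
    bias_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BIAS_PROPORTIONS)
    )
    conditions: tuple[str, ...] = ("normal",)
    deterministic_counts: bool = False
    call_depth: int = 20
    call_noise_rate: float = 0.0

    def validate(self) -> None:
        if not 0.0 <= self.divergence_rate <= 1.0:
            raise ValueError("divergence_rate must be in [0, 1]")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.fold_change <= 1:
            raise ValueError("fold_change must be > 1")
        for name, props in (("category", self.category_proportions),
                            ("bias", self.bias_proportions)):
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} proportions sum to {total}, expected 1")
            if any(p < 0 for p in props.values()):
                raise ValueError(f"{name} proportions must be non-negative")

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream: deterministic per (seed, stream)."""
        digest = int.from_bytes(stream.encode(), "big") % (2**32)
        return np.random.default_rng([self.seed, digest])

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conditions"] = list(self.conditions)
        return d


@dataclass
class SimRead:
    read_id: str
    origin: str  # 'A' or 'B'
    contig: str
    pos: int  # 1-based leftmost
    seq: str


@dataclass
class SimTruth:
    snp_truth: list[tuple[str, int, str, str]] = field(default_factory=list)
    read_truth: dict[str, str] = field(default_factory=dict)
    gene_truth: dict[str, dict[str, str]] = field(default_factory=dict)
    gene_fractions: dict[str, dict[str, float]] = field(default_factory=dict)


class SizingError(ValueError):
    """Genome too small to host the requested gene models."""


# ---------------------------------------------------------------------------
# Genomes and gene models

_GENE_UTR5 = 60
_GENE_INTRON = 120
_GENE_UTR3 = 60
_GENE_CDS = 300  # multiple of 3, split across two exons
_GENE_GAP = 200


def _gene_span() -> int:
    return _GENE_UTR5 + _GENE_CDS + _GENE_INTRON + _GENE_UTR3


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """ATG + random non-stop codons + one stop codon."""
    sense = [c for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
             if c not in STOP_CODONS and c != "ATG"]
    body = rng.choice(len(sense), size=n_codons - 2)
    stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
    return "ATG" + "".join(sense[i] for i in body) + stop


def simulate_ancestral_genomes(
    config: SimConfig,
) -> tuple[Genome, Genome, list[GeneModel], list[tuple[str, int, str, str]]]:
    """Build genome A, a point-substitution-diverged genome B, and gene models.

    Genes tile the front of each contig with a fixed two-exon structure
    (5'UTR + CDS/intron/CDS + 3'UTR), alternating strand. Genome B differs
    from A at positions substituted independently at ``divergence_rate``,
    uniformly among the three alternative bases.
    """
    config.validate()
    span = _gene_span()
    per_contig = [config.n_genes // config.n_contigs + (1 if i < config.n_genes % config.n_contigs else 0)
                  for i in range(config.n_contigs)]
    contig_len = config.genome_length // config.n_contigs
    if max(per_contig) * (span + _GENE_GAP) + _GENE_GAP > contig_len:
        raise SizingError(
            f"genome_length {config.genome_length} too small for {config.n_genes} genes"
        )

    rng = config.rng("genomes")
    contigs_a: dict[str, str] = {}
    genes: list[GeneModel] = []
    for ci in range(config.n_contigs):
        name = f"chr{ci + 1}"
        seq = rng.choice(4, size=contig_len)
        arr = BASES[seq].tobytes().decode()
        arr = list(arr)
        offset = _GENE_GAP
        for gi in range(per_contig[ci]):
            gene_id = f"gene{ci + 1:02d}g{gi + 1:04d}"
            strand = "+" if (gi % 2 == 0) else "-"
            start = offset + 1  # 1-based
            u5_s, u5_e = start, start + _GENE_UTR5 - 1
            cds1_len = (_GENE_CDS // 2 // 3) * 3
            cds2_len = _GENE_CDS - cds1_len
            c1_s, c1_e = u5_e + 1, u5_e + cds1_len
            in_s, in_e = c1_e + 1, c1_e + _GENE_INTRON
            c2_s, c2_e = in_e + 1, in_e + cds2_len
            u3_s, u3_e = c2_e + 1, c2_e + _GENE_UTR3
            end = u3_e
            exons = ((u5_s, c1_e), (c2_s, u3_e))
            cds = ((c1_s, c1_e), (c2_s, c2_e))
            transcript_cds = _random_cds(_GENE_CDS // 3, rng)
            genomic = transcript_cds if strand == "+" else revcomp(transcript_cds)
            arr[c1_s - 1 : c1_e] = genomic[:cds1_len]
            arr[c2_s - 1 : c2_e] = genomic[cds1_len:]
            genes.append(
                GeneModel(gene_id, name, start, end, strand, exons, cds)
            )
            offset = end + _GENE_GAP
        contigs_a[name] = "".join(arr)

    genome_a = Genome(contigs_a)

    # diverge: independent per-site substitution
    rng_div = config.rng("divergence")
    contigs_b: dict[str, str] = {}
    snp_truth: list[tuple[str, int, str, str]] = []
    for name, seq in contigs_a.items():
        a = np.frombuffer(seq.encode(), dtype="S1")
        idx = np.searchsorted(BASES, a)  # A/C/G/T -> 0..3 (sorted order holds)
        mask = rng_div.random(len(a)) < config.divergence_rate
        shift = rng_div.integers(1, 4, size=len(a))
        new_idx = np.where(mask, (idx + shift) % 4, idx)
        b = BASES[new_idx].tobytes().decode()
        contigs_b[name] = b
        for p in np.flatnonzero(mask):
            snp_truth.append((name, int(p) + 1, seq[p], b[p]))

    return genome_a, Genome(contigs_b), genes, snp_truth


# ---------------------------------------------------------------------------
# Reads and alignments

def simulate_reads(
    genome_a: Genome, genome_b: Genome, config: SimConfig
) -> tuple[list[SimRead], dict[str, str]]:
    """Draw ungapped L-mers from either genome with i.i.d. base errors."""
    L = config.read_length
    shortest = min(len(s) for s in genome_a.contigs.values())
    if L > shortest:
        raise ValueError(f"read_length {L} exceeds shortest contig ({shortest})")
    rng = config.rng("reads")
    names = list(genome_a.contigs)
    lengths = np.array([len(genome_a.contigs[n]) for n in names], dtype=float)
    weights = lengths / lengths.sum()
    reads: list[SimRead] = []
    read_truth: dict[str, str] = {}
    for i in range(config.n_reads):
        origin = "A" if rng.random() < 0.5 else "B"
        ci = rng.choice(len(names), p=weights)
        contig = names[ci]
        src = (genome_a if origin == "A" else genome_b).contigs[contig]
        pos = int(rng.integers(1, len(src) - L + 2))
        seq = list(src[pos - 1 : pos - 1 + L])
        if config.error_rate > 0:
            err = np.flatnonzero(rng.random(L) < config.error_rate)
            for j in err:
                alternatives = [b for b in "ACGT" if b != seq[j]]
                seq[j] = alternatives[rng.integers(3)]
        rid = f"read{i:07d}"
        reads.append(SimRead(rid, origin, contig, pos, "".join(seq)))
        read_truth[rid] = origin
    return reads, read_truth


def align_reads_naive(reads: list[SimRead], genome: Genome) -> list[ReadAlignment]:
    """Oracle aligner: place each read at its true locus, NM = Hamming distance."""
    out = []
    for r in reads:
        if r.contig not in genome:
            raise ValueError(f"read {r.read_id}: contig {r.contig} not in genome")
        ref = genome.fetch(r.contig, r.pos, r.pos + len(r.seq) - 1)
        if len(ref) < len(r.seq):
            raise ValueError(f"read {r.read_id} locus outside genome")
        nm = sum(a != b for a, b in zip(r.seq, ref))
        out.append(ReadAlignment(r.read_id, r.contig, r.pos, mapped=True, nm=nm))
    return out


# ---------------------------------------------------------------------------
# SNP call emission

def emit_snp_calls(
    genome_a: Genome,
    genome_b: Genome,
    snp_truth: list[tuple[str, int, str, str]],
    config: SimConfig,
) -> tuple[list[SnpCall], list[SnpCall]]:
    """Emit pileup-style call tables: ancestor-B-vs-A and hybrid-vs-A.

    Truth SNPs get a near-1 variant frequency in the B table (homogenic) and
    a near-0.5 frequency in the hybrid table (heterogenic). Optional noise
    calls at non-SNP sites are added at ``call_noise_rate`` per site.
    """
    rng = config.rng("calls")
    depth = config.call_depth
    calls_b: list[SnpCall] = []
    calls_h: list[SnpCall] = []
    for contig, pos, ref, var in snp_truth:
        calls_b.append(SnpCall(contig, pos, ref, var, depth, float(rng.uniform(0.90, 1.0))))
        calls_h.append(SnpCall(contig, pos, ref, var, depth, float(rng.uniform(0.40, 0.60))))
    if config.call_noise_rate > 0:
        truth_pos = {(c, p) for c, p, _, _ in snp_truth}
        for target in (calls_b, calls_h):
            for contig, seq in genome_a.contigs.items():
                n_noise = rng.binomial(len(seq), config.call_noise_rate)
                sites = rng.choice(len(seq), size=n_noise, replace=False)
                for p0 in sites:
                    pos = int(p0) + 1
                    if (contig, pos) in truth_pos:
                        continue
                    ref = seq[p0]
                    var = [b for b in "ACGT" if b != ref][rng.integers(3)]
                    target.append(
                        SnpCall(contig, pos, ref, var, depth, float(rng.uniform(0.0, 1.0)))
                    )
    key = lambda c: (c.contig, c.pos)
    return sorted(calls_b, key=key), sorted(calls_h, key=key)


# ---------------------------------------------------------------------------
# Count matrices with planted categories

def _plant_fractions(
    add_cat: str, bias_cat: str, base: float, fold: float, rng: np.random.Generator
) -> dict[str, float]:
    """Return true expression fractions for the four groups of one gene.

    The bias category fixes the ancestral ratio (equal or ``fold`` apart) and
    the homoeolog split inside the hybrid; the additivity category fixes the
    hybrid total relative to the ancestors.
    """
    F = fold
    # ancestral direction: for ELD the dominated parent is the lower one so the
    # hybrid total sits far from the mid-ancestral value; otherwise random.
    if add_cat == "ELD_BD":
        hi_is_bd = False
    elif add_cat == "ELD_BS":
        hi_is_bd = True
    else:
        hi_is_bd = bool(rng.random() < 0.5)

    if bias_cat in _BIASED_ANCESTOR_CATEGORIES:
        f_bd, f_bs = (base * F, base) if hi_is_bd else (base, base * F)
    else:
        if add_cat in ("ELD_BD", "ELD_BS"):
            raise ValueError(f"{add_cat} requires a biased-ancestor bias category")
        f_bd, f_bs = base, base

    if add_cat == "ADDITIVE":
        total = (f_bd + f_bs) / 2.0
    elif add_cat == "ELD_BD":
        total = f_bd
    elif add_cat == "ELD_BS":
        total = f_bs
    elif add_cat == "TRANSGRESSIVE_UP":
        total = F * max(f_bd, f_bs)
    elif add_cat == "TRANSGRESSIVE_DOWN":
        total = min(f_bd, f_bs) / F
    else:
        raise ValueError(f"unknown additivity category {add_cat}")

    # hybrid homoeolog split r = BhBd : BhBs
    anc_dir = 1 if f_bd > f_bs else (-1 if f_bd < f_bs else 0)
    if bias_cat == "NO_BIAS" or bias_cat == "BIAS_LOST":
        r = 1.0
    elif bias_cat == "BIAS_RETAINED":
        r = F if anc_dir > 0 else 1.0 / F
    elif bias_cat == "BIAS_REVERSED":
        r = 1.0 / F if anc_dir > 0 else F
    elif bias_cat == "BIAS_GAINED":
        r = F if rng.random() < 0.5 else 1.0 / F
    else:
        raise ValueError(f"unknown bias category {bias_cat}")
    w = r / (1.0 + r)
    return {"BD": f_bd, "BS": f_bs, "BH_BD": total * w, "BH_BS": total * (1.0 - w)}


def _sample_categories(config: SimConfig, rng: np.random.Generator) -> list[tuple[str, str]]:
    add_names = list(config.category_proportions)
    add_p = np.array([config.category_proportions[k] for k in add_names])
    bias_names = list(config.bias_proportions)
    bias_p = np.array([config.bias_proportions[k] for k in bias_names])
    out = []
    for _ in range(config.n_genes):
        add_cat = add_names[rng.choice(len(add_names), p=add_p)]
        if add_cat in ("ELD_BD", "ELD_BS"):
            ok = [i for i, b in enumerate(bias_names) if b in _BIASED_ANCESTOR_CATEGORIES]
            p = bias_p[ok]
            if p.sum() == 0:
                p = np.ones(len(ok))
            bias_cat = bias_names[ok[rng.choice(len(ok), p=p / p.sum())]]
        else:
            bias_cat = bias_names[rng.choice(len(bias_names), p=bias_p)]
        out.append((add_cat, bias_cat))
    return out


def _nb_draw(mean: np.ndarray, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Mean/dispersion NB via gamma-Poisson; phi = 0 degenerates to Poisson."""
    if phi == 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / phi, scale=mean * phi)
    return rng.poisson(lam)


def simulate_counts(
    gene_models: list[GeneModel], config: SimConfig
) -> tuple["CountSet", dict[str, dict[str, str]], dict[str, dict[str, float]]]:
    """Generate NB count matrices for BD/BS/BH_BD/BH_BS with planted truth.

    Returns (count set, gene_truth, gene_fractions). In deterministic mode the
    counts are rounded means, enabling exact downstream assertions.
    """
    from .quant import CountSet  # local import to avoid a cycle

    config.validate()
    if len(gene_models) != config.n_genes:
        raise ValueError("gene_models length disagrees with config.n_genes")
    rng = config.rng("counts")
    categories = _sample_categories(config, rng)
    base = np.exp(rng.normal(config.mu_log, config.sigma_log, size=config.n_genes))
    if config.baseline_floor > 0:
        base = np.maximum(base, config.baseline_floor)

    gene_ids = [g.gene_id for g in gene_models]
    gene_truth = {}
    gene_fractions = {}
    frac = {grp: np.empty(config.n_genes) for grp in GROUPS}
    for i, (gid, (add_cat, bias_cat)) in enumerate(zip(gene_ids, categories)):
        f = _plant_fractions(add_cat, bias_cat, float(base[i]), config.fold_change, rng)
        for grp in GROUPS:
            frac[grp][i] = f[grp]
        gene_truth[gid] = {"additivity": add_cat, "bias": bias_cat}
        gene_fractions[gid] = f

    for grp in GROUPS:
        total = frac[grp].sum()
        if total > 1.0:
            warnings.warn(f"planted fractions for {grp} sum to {total:.3f}; renormalizing")
            frac[grp] /= total
            for i, gid in enumerate(gene_ids):
                gene_fractions[gid][grp] = float(frac[grp][i])

    columns = {}
    meta_rows = []
    libs = {}
    N = config.library_size
    for grp in GROUPS:
        # the two hybrid subgenome columns are one sorted library of N reads,
        # so each carries half the library size; summing them (the hybrid
        # total) restores a library of N and an RPM equal to the planted total
        lib = N // 2 if grp.startswith("BH_") else N
        for cond in config.conditions:
            for rep in range(1, config.n_replicates + 1):
                sample = f"{grp}_{cond}_r{rep}"
                mean = frac[grp] * N
                if config.deterministic_counts:
                    counts = np.rint(mean).astype(int)
                else:
                    counts = _nb_draw(mean, config.dispersion, rng)
                columns[sample] = counts
                libs[sample] = lib
                meta_rows.append((sample, grp, cond, rep))

    counts_df = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene"))
    samples = pd.DataFrame(
        [(g, c, r) for _, g, c, r in meta_rows],
        index=pd.Index([s for s, *_ in meta_rows], name="sample"),
        columns=["group", "condition", "replicate"],
    )
    library_sizes = pd.Series(libs, index=samples.index, name="library_size")
    return CountSet(counts_df, samples, library_sizes), gene_truth, gene_fractions


# ---------------------------------------------------------------------------
# Term annotations (plumbing for the enrichment stage)

def simulate_annotations(
    gene_ids: list[str],
    config: SimConfig,
    n_terms: int = 10,
    genes_per_term: int = 10,
    enriched_genes: Optional[list[str]] = None,
) -> pd.DataFrame:
    """Random gene→term table, optionally with one term planted on a gene set."""
    rng = config.rng("annotations")
    rows = []
    for t in range(n_terms):
        term = f"TERM:{t:04d}"
        members = rng.choice(len(gene_ids), size=min(genes_per_term, len(gene_ids)), replace=False)
        rows.extend((gene_ids[m], term) for m in members)
    if enriched_genes:
        rows.extend((g, "TERM:PLANTED") for g in enriched_genes)
    return pd.DataFrame(rows, columns=["gene", "term"])


def snp_truth_to_homoeosnps(snp_truth: list[tuple[str, int, str, str]]) -> list[HomoeoSnp]:
    return [HomoeoSnp(c, p, a, b) for c, p, a, b in snp_truth]
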