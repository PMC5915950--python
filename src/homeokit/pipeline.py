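"""End-to-end orchestration of the synthetic study and analysis stages.

Stages run in dependency order, each writing plain-text artifacts plus a
manifest entry with a SHA-256 checksum and the parameters used, so reruns
with the same config are byte-identical and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam
import yaml

from . import _io, simulate as sim
from .classify import ClassifyOptions, classify_transcriptome
from .divergence import DivergenceConfig, divergence_time, extract_cds_pair, ng86_ka_ks
from .enrichment import fisher_enrichment, filter_large_terms, read_annotations
from .models import Origin
from .quant import CountSet, count_reads
from .snpmap import Thresholds, annotate_effect, effects_to_frame, identify_homoeologous_snps, summarize_effects
from .sorter import sort_reads, sorted_reads_to_frame
from .virtualgenome import build_virtual_genome, verify_substitutions

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "snpmap", "virtualize", "sort", "count", "classify", "kaks", "enrich")


@dataclass
class RunConfig:
    out_dir: Path
    seed: int = 0
    sim: sim.SimConfig = field(default_factory=sim.SimConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    alpha: float = 0.001
    rpm_threshold: float = 1.0
    substitution_rate: float = 6.1e-9
    max_term_size: int = 3000
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.sim.seed = self.seed

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        sim_cfg = sim.SimConfig(**raw.pop("sim", {}))
        thr = Thresholds(**raw.pop("thresholds", {}))
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(sim=sim_cfg, thresholds=thr, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineRun:
    def __init__(self, config: RunConfig):
        self.config = config
        self.out = config.out_dir
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: dict[str, dict] = {}

    def path(self, name: str) -> Path:
        return self.out / name

    def record(self, stage: str, files: list[Path], params: dict) -> None:
        self.manifest[stage] = {
            "outputs": {f.name: _sha256(f) for f in files},
            "params": params,
        }
        logger.info("stage %s done: %s", stage, [f.name for f in files])

    def run(self) -> dict:
        cfg = self.config
        done: list[str] = []
        try:
            for stage in ALL_STAGES:
                if stage in cfg.stages:
                    getattr(self, f"stage_{stage}")()
                    done.append(stage)
        except Exception:
            self.manifest["status"] = {"completed": done, "failed_stage": stage}
            _io.write_json(self.manifest, self.path("manifest.json"))
            raise
        self.manifest["status"] = {"completed": done, "failed_stage": None}
        _io.write_json(self.manifest, self.path("manifest.json"))
        return self.manifest

    # -- stages -------------------------------------------------------------

    def stage_simulate(self) -> None:
        cfg = self.config
        genome_a, genome_b, genes, snp_truth = sim.simulate_ancestral_genomes(cfg.sim)
        reads, read_truth = sim.simulate_reads(genome_a, genome_b, cfg.sim)
        aligns_a = sim.align_reads_naive(reads, genome_a)
        aligns_b = sim.align_reads_naive(reads, genome_b)
        calls_b, calls_h = sim.emit_snp_calls(genome_a, genome_b, snp_truth, cfg.sim)
        count_set, gene_truth, gene_fractions = sim.simulate_counts(genes, cfg.sim)
        transgressive = [
            g for g, t in gene_truth.items() if t["additivity"].startswith("TRANSGRESSIVE")
        ]
        annotations = sim.simulate_annotations(
            [g.gene_id for g in genes], cfg.sim, enriched_genes=transgressive
        )

        p = self.path
        _io.write_fasta(genome_a, p("genome_a.fasta"))
        _io.write_fasta(genome_b, p("genome_b_truth.fasta"))
        _io.write_gff3(genes, p("genes.gff3"))
        _io.write_snp_calls(calls_b, p("calls_b_vs_a.tsv"))
        _io.write_snp_calls(calls_h, p("calls_h_vs_a.tsv"))
        seqs = {r.read_id: r.seq for r in reads}
        _io.write_sam(
            [(a, seqs[a.read_id]) for a in aligns_a], genome_a.lengths(), p("aligns_a.sam")
        )
        _io.write_sam(
            [(a, seqs[a.read_id]) for a in aligns_b], genome_b.lengths(), p("aligns_b.sam")
        )
        _io.write_counts(
            count_set.counts, count_set.samples, count_set.library_sizes,
            p("counts.tsv"), p("samples.tsv"),
        )
        annotations.to_csv(p("annotations.tsv"), sep="\t", index=False)
        _io.write_json(
            {
                "snp_truth": [list(t) for t in snp_truth],
                "read_truth": read_truth,
                "gene_truth": gene_truth,
                "gene_fractions": gene_fractions,
            },
            p("truth.json"),
        )
        with open(p("config.yaml"), "w") as fh:
            yaml.safe_dump(cfg.sim.to_dict(), fh, sort_keys=True)
        self.record(
            "simulate",
            [p(n) for n in (
                "genome_a.fasta", "genome_b_truth.fasta", "genes.gff3",
                "calls_b_vs_a.tsv", "calls_h_vs_a.tsv", "aligns_a.sam", "aligns_b.sam",
                "counts.tsv", "samples.tsv", "annotations.tsv", "truth.json", "config.yaml",
            )],
            cfg.sim.to_dict(),
        )

    def stage_snpmap(self) -> None:
        p = self.path
        calls_b = _io.read_snp_calls(p("calls_b_vs_a.tsv"))
        calls_h = _io.read_snp_calls(p("calls_h_vs_a.tsv"))
        thr = self.config.thresholds
        snps = identify_homoeologous_snps(calls_b, calls_h, thr)
        _io.write_homoeosnps(snps, p("homoeosnps.tsv"))
        genes = _io.read_gff3(p("genes.gff3"))
        genome_a = _io.read_fasta(p("genome_a.fasta"))
        effects = [annotate_effect(s, genes, genome_a) for s in snps]
        effects_to_frame(effects).to_csv(p("effects.tsv"), sep="\t", index=False)
        summary = summarize_effects(effects)
        _io.write_json(summary, p("effect_summary.json"))
        self.record(
            "snpmap",
            [p("homoeosnps.tsv"), p("effects.tsv"), p("effect_summary.json")],
            {"min_depth": thr.min_depth, "homo_freq": thr.homo_freq,
             "het_low": thr.het_low, "het_high": thr.het_high},
        )

    def stage_virtualize(self) -> None:
        p = self.path
        genome_a = _io.read_fasta(p("genome_a.fasta"))
        snps = _io.read_homoeosnps(p("homoeosnps.tsv"))
        virtual = build_virtual_genome(genome_a, snps, strict=True)
        _io.write_fasta(virtual, p("virtual_genome.fasta"))
        report = verify_substitutions(genome_a, virtual, snps)
        _io.write_json(
            {"n_expected": report.n_expected, "n_applied": report.n_applied,
             "n_mismatches": len(report.mismatches)},
            p("virtual_report.json"),
        )
        if not report.ok:
            raise RuntimeError("virtual genome verification failed")
        self.record(
            "virtualize",
            [p("virtual_genome.fasta"), p("virtual_report.json")],
            {"strict": True, "n_snps": len(snps)},
        )

    def stage_sort(self) -> None:
        p = self.path
        aligns_a = _io.read_sam(p("aligns_a.sam"))
        aligns_b = _io.read_sam(p("aligns_b.sam"))
        sorted_reads, summary = sort_reads(aligns_a, aligns_b)
        sorted_reads_to_frame(sorted_reads).to_csv(p("sorted_reads.tsv"), sep="\t", index=False)
        _io.write_json(summary.to_dict(), p("sort_summary.json"))
        self.record(
            "sort", [p("sorted_reads.tsv"), p("sort_summary.json")], {"max_nm": None}
        )

    def stage_count(self) -> None:
        p = self.path
        genes = _io.read_gff3(p("genes.gff3"))
        origins = pd.read_csv(p("sorted_reads.tsv"), sep="\t", index_col="read_id")
        loci: dict[str, tuple[str, int, int]] = {}
        with pysam.AlignmentFile(str(p("aligns_a.sam")), "r", check_sq=False) as sam:
            for rec in sam:
                if not rec.is_unmapped:
                    loci[rec.query_name] = (
                        rec.reference_name,
                        rec.reference_start + 1,
                        rec.reference_start + rec.query_length,
                    )
        columns = {}
        summaries = {}
        for label, origin in (("BH_BD", Origin.ORIGIN_A.value), ("BH_BS", Origin.ORIGIN_B.value)):
            ids = origins.index[origins["origin"] == origin]
            read_loci = [(rid, *loci[rid]) for rid in ids if rid in loci]
            col, stats = count_reads(read_loci, genes)
            columns[label] = col
            summaries[label] = stats
        pd.DataFrame(columns).to_csv(p("hybrid_counts.tsv"), sep="\t", index_label="gene")
        _io.write_json(summaries, p("count_summary.json"))
        self.record("count", [p("hybrid_counts.tsv"), p("count_summary.json")], {})

    def stage_classify(self) -> None:
        p = self.path
        counts, meta, libs = _io.read_counts(p("counts.tsv"), p("samples.tsv"))
        cs = CountSet(counts, meta, libs)
        opts = ClassifyOptions(alpha=self.config.alpha, rpm_threshold=self.config.rpm_threshold)
        table = classify_transcriptome(cs, opts)
        table.to_csv(p("classification.tsv"), sep="\t")
        self.record(
            "classify", [p("classification.tsv")],
            {"alpha": self.config.alpha, "rpm_threshold": self.config.rpm_threshold},
        )

    def stage_kaks(self) -> None:
        p = self.path
        genome_a = _io.read_fasta(p("genome_a.fasta"))
        virtual = _io.read_fasta(p("virtual_genome.fasta"))
        genes = _io.read_gff3(p("genes.gff3"))
        rows = []
        ks_values = []
        for g in genes:
            cds_a, cds_b = extract_cds_pair(g, genome_a, virtual)
            est = ng86_ka_ks(cds_a, cds_b, gene=g.gene_id)
            rows.append((g.gene_id, est.s_sites, est.n_sites, est.s_diffs, est.n_diffs,
                         est.ka, est.ks, est.omega))
            if est.ks is not None:
                ks_values.append(est.ks)
        pd.DataFrame(
            rows, columns=["gene", "S", "N", "Sd", "Nd", "ka", "ks", "omega"]
        ).to_csv(p("kaks.tsv"), sep="\t", index=False)
        dconf = DivergenceConfig(rate=self.config.substitution_rate)
        mean_ks = sum(ks_values) / len(ks_values) if ks_values else None
        t_years = divergence_time(ks_values, dconf) if ks_values else None
        _io.write_json(
            {"mean_ks": mean_ks, "t_years": t_years, "rate": dconf.rate,
             "n_genes": len(rows), "n_usable_ks": len(ks_values)},
            p("kaks_summary.json"),
        )
        self.record(
            "kaks", [p("kaks.tsv"), p("kaks_summary.json")],
            {"rate": dconf.rate, "method": dconf.method},
        )

    def stage_enrich(self) -> None:
        p = self.path
        classification = pd.read_csv(p("classification.tsv"), sep="\t", index_col="gene")
        annotations = read_annotations(p("annotations.tsv"))
        genes = _io.read_gff3(p("genes.gff3"))
        population = [g.gene_id for g in genes]
        study = sorted(set(classification.index[classification["additivity"] != "ADDITIVE"]))
        kept = filter_large_terms(annotations, self.config.max_term_size)
        result = fisher_enrichment(study, kept, population)
        result.to_csv(p("enrichment.tsv"), sep="\t", index=False)
        self.record(
            "enrich", [p("enrichment.tsv")],
            {"max_term_size": self.config.max_term_size, "n_study": len(study)},
        )


def run_pipeline(config: RunConfig) -> dict:
    return PipelineRun(config).run()
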