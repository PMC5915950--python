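# homeokit

Homoeolog-resolution transcriptome analysis for allopolyploids and their two
diploid ancestors, exercised end-to-end on a truth-labelled synthetic data
generator. The toolkit covers:

- **Homoeologous SNP mapping** — classify pileup-style SNP calls as
  homogenic (second ancestor vs reference) or heterogenic (hybrid vs
  reference) and intersect them into a homoeologous SNP map, with a minimal
  coding-effect annotator (synonymous/nonsynonymous, start-loss, stop
  gain/loss, splice sites).
- **Virtual ancestral genome** — substitute the mapped alleles into the
  reference FASTA to obtain coordinates-preserving homoeolog sequences, with
  an independent verification pass.
- **Subgenome read sorting** — assign each hybrid RNA-seq read to its
  subgenome of origin by comparing per-alignment mismatch counts (SAM `NM`
  tags) against both genomes; ties stay unclassified.
- **Expression quantification** — exon-union read counting, RPM, the
  "RPM ≥ 1 in all replicates" expressed filter, mid-ancestral pseudo-samples
  (summed counts and library sizes), and Pearson sample-correlation matrices.
- **Additivity / bias classification** — an explicit negative-binomial Wald
  test (median-of-ratios size factors, moment dispersion, delta-method SE)
  drives five group comparisons at FDR ≤ 0.001 and maps the significance
  relations onto additive / expression-level-dominance / transgressive
  categories and retained/lost/gained/reversed homoeolog-bias categories.
- **Divergence dating** — NG86 Ka/Ks with Jukes–Cantor correction per
  homoeologous CDS pair and T = Ks/2λ dating (λ = 6.1 × 10⁻⁹ by default).
- **Term enrichment** — one-sided Fisher exact tests against an annotated
  population with exclusion of terms covering > 3000 genes and BH control.
- **Synthetic study generator** — diverged genome pair, gene models, reads
  of known origin, oracle alignments, SNP call tables, and NB count matrices
  with planted category truth, all reproducible from one seed.

## CLI

Run the whole synthetic pipeline (simulate → snpmap → virtualize → sort →
count → classify → kaks → enrich) into one output directory:

```sh
homeokit run-all --seed 1 --out-dir run1
```

Each stage writes plain-text artifacts (FASTA/GFF3/SAM/TSV/JSON) plus a
`manifest.json` with SHA-256 checksums and the parameters used; rerunning
with the same config is byte-identical. Stages are also available as
standalone commands operating on files, e.g.:

```sh
homeokit sort --sam-a run1/aligns_a.sam --sam-b run1/aligns_b.sam \
    --out sorted.tsv --summary sort_summary.json
homeokit classify --counts run1/counts.tsv --meta run1/samples.tsv \
    --out classes.tsv --alpha 0.001
homeokit kaks --genome run1/genome_a.fasta --virtual run1/virtual_genome.fasta \
    --gff run1/genes.gff3 --out kaks.tsv
```

See `homeokit --help` for the full list (`simulate`, `snpmap`, `virtualize`,
`sort`, `classify`, `kaks`, `enrich`, `run-all`). A YAML config with
per-stage sections can be passed to `run-all --config`; CLI flags override
it.

## Conventions

- Positions are 1-based at every I/O boundary; sequence arithmetic is
  0-based internally.
- Pairwise relations are reported first-named-group versus second: `GT`
  means the first group is significantly higher at the FDR threshold
  (inclusive, ≤).
- Significance thresholds, pseudo-counts, and frequency windows are
  configurable and recorded in run manifests.
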