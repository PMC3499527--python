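# polyest

Homoeolog-aware EST analysis for allotetraploid transcriptomes.

Tetraploid cotton (*Gossypium hirsutum* "Gh" and *G. barbadense* "Gb")
carries two ancestral sub-genomes, A and D. When fiber ESTs from both
species are co-assembled, each contig mixes four closely related sequences:
the A- and D-sub-genome homoeologs of each genotype. Working with such
assemblies requires separating two very different kinds of sequence
variant, and extracting expression and marker information that respects the
mixture. `polyest` implements that computational layer as a reusable,
tested pipeline:

* **Sub-genome read tagging** — each read is scored against A-like and
  D-like diploid progenitor transcript panels with an 11-mer-seeded,
  ungapped local aligner (score = matches − mismatches). A strictly better
  score ≥ 30 on both panels assigns an A or D tag; equal scores or
  one-sided hits stay `unknown`.
* **Digital gene expression (DGE)** — read counts per contig per library
  (genotype × fiber stage, optionally × sub-genome tag), normalised per
  10,000 reads. For a contig with counts *x_j* across libraries of sizes
  *N_j*, heterogeneity is measured by the log-likelihood statistic
  *R = Σ_j x_j ln(x_j / (N_j f))* with *f = Σx_j / ΣN_j* (Stekel, Git &
  Falciani); pairwise significance uses the two-sided Fisher's exact test,
  and a contig is called differential when p < 0.05 and the normalised fold
  change is ≥ 2. All pairwise factorial comparisons (stage, genotype, tag;
  overall and nested) are enumerated, plus a cross-platform
  direction-concordance tally.
* **SNP mining** — from per-position allele depths stratified by genotype.
  A genotype is polymorphic at a position when its depth is ≥ 6 and a minor
  allele reaches 10% of that depth with ≥ 2 reads. Dual-coverage positions
  partition into: case A (both genotypes polymorphic — a homoeo-SNP, fixed
  between sub-genomes, not a marker), cases B/C (only Gh / only Gb
  polymorphic — allelic, inter-genotypic SNPs), and case D (both
  monomorphic for different alleles — each genotype expressing a single
  sub-genome copy). Ts/Tv accounting, SNP densities, 60-bp-flank export and
  VCF output included.
* **SSR mining** — MISA-parameterised microsatellite scan (≥ 10 / 6 / 5
  repeats for mono- / di- / tri-to-hexanucleotide motifs, compound repeats
  within 100 bp), canonical motif classes, and design-candidate filtering.
* **Allele-specific primer triplets** — for biallelic inter-genotypic
  SNPs: two forward primers ending on the alternative alleles, tailed with
  15 vs 5 bases so products differ by 10 bp, each with a distinct
  destabilizing transversion at position −4 from the 3′ end, plus a common
  reverse primer.
* **Synthetic data** — a seeded generator for a two-genotype, two-stage
  tetraploid transcriptome with planted homoeo and allelic substitutions,
  silenced homoeo-copies, planted microsatellites, stage-differential
  expression and 454-like reads (mean 353 bp), with full truth tables, so
  every stage is testable without any download.

## Worked example

Simulate a small dataset with 4-fold expression changes planted in ~20% of
gene copies, and test stage 10 vs stage 22:

```python
from polyest.sim import SimConfig, simulate_transcriptome, simulate_counts
from polyest import dge

cfg = SimConfig(n_genes=50, reads_per_library=5000,
                de_fraction=0.2, de_fold=4.0, seed=7)
truth = simulate_transcriptome(cfg)
counts = simulate_counts(truth)
spec = dge.ComparisonSpec("10_vs_22", ("Gh10", "Gb10"), ("Gh22", "Gb22"))
res = dge.compare_groups(counts, spec, alpha=0.05, min_fold=2.0)
```

The first flagged contigs:

```
         x1  x2    fold   r_stat       p    flag
contig
gene02   45  18  2.5000   6.6353  0.0009  group1
gene04    6  22  0.2727   6.6881  0.0037  group2
gene06   16  45  0.3556   9.6910  0.0003  group2
gene07  275  87  3.1609  52.5591  0.0000  group1
gene08   22  52  0.4231   7.0883  0.0006  group2
```

`x1`/`x2` are the pooled stage-10 and stage-22 read counts, `fold` the
normalised stage-10/stage-22 ratio, `r_stat` the R statistic across the
four libraries, `p` the Fisher p, and `flag` the direction of significant
≥ 2-fold difference (`group1` = higher at 10 dpa). On this dataset 19
contigs are flagged and 19 of the 23 genes with a planted change are
recovered in the correct direction (the misses are low-expression genes).

## Analysis drivers

The `analysis/` scripts run the pipeline step by step on the default
synthetic dataset (200 genes, 20,000 reads per library), writing tables
under `results/`:

```sh
python analysis/01_simulate.py      # dataset + truth under results/data/
python analysis/02_filter_and_tag.py
python analysis/03_dge.py
python analysis/04_snp_mining.py
python analysis/05_ssr_mining.py
python analysis/06_report.py
```

The same stages are available as `polyest` CLI subcommands
(`simulate`, `filter`, `tag`, `dge`, `ssr`, `report`, `all`), and
`polyest all` runs everything from one YAML configuration.

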