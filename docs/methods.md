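# Methods

This note records the models, conventions and numerical choices behind
`polyest`, and what the synthetic-data experiments do and do not establish.

## The synthetic transcriptome model

Each gene descends from a random ancestral transcript (uniform base
composition, length uniform on 600–1,600 bp, mean 1,100 bp — the scale of
assembled fiber contigs). Four copies exist per gene: sub-genome copies A
and D in each of genotypes Gh and Gb.

* **Homoeo-substitutions** separate the A and D copies and are shared by
  both genotypes; their count per gene is binomial with rate 1/80 per
  consensus bp.
* **Allelic substitutions** separate the genotypes; each lands on one
  randomly chosen copy in one randomly chosen genotype, at rate 1/108 per
  consensus bp. Homoeo and allelic positions are drawn jointly without
  replacement, so the classes are disjoint by construction and every
  planted position indexes a real base difference.
* **Substitutions are uniform** over the three alternative bases.
  Transitions are deliberately not favoured: the ~61% transition share seen
  in real plant data is an observation, and keeping the model uniform means
  the Ts/Tv tally can be verified against its own expectation of 1/3 rather
  than against a tuned input.
* **Silencing**: a configurable fraction of genes (default 5%) receives a
  silencing event. With probability 0.7 a single random genotype silences
  one random copy; with probability 0.3 both genotypes silence opposite
  copies — the pattern that converts homoeo positions into fixed
  inter-genotypic differences (class case D). Silencing is zero expression,
  not sequence deletion.
* **Expression**: one lognormal(σ = 1) base level per gene, shared by all
  four copies — balanced homoeolog expression except where silenced.
  A configurable fraction of gene copies (default 10%) is
  stage-differential: the gene draws an up-stage once, and each selected
  copy's level is multiplied by the fold (default 4) at that stage in both
  genotypes.
* **Microsatellites**: a fraction of genes (default 15%) carries one
  planted perfect repeat written into the ancestor (unit length weighted
  like transcriptome SSR surveys, di- and trinucleotides dominant; repeat
  counts at the detection thresholds plus 0–5), so the SSR stage has true
  positives to find.
* **Reads**: per library (genotype × stage), read counts per (gene, copy)
  are multinomial with weights proportional to expression. Lengths are
  truncated normal (mean 353 bp, sd 40, resampled until ≥ 1 bp, capped at
  gene length); starts are uniform; errors are uniform substitutions
  (default 0.5% per bp). Each read records its true placement on the
  gene's ancestral coordinates, so assembly is bypassed: each gene directly
  yields one contig alignment whose consensus is the ancestral (A-copy
  base) sequence.

What the generator does **not** emulate: 454 homopolymer errors, indels,
chimeric reads, quality values, mis-assembly and paralog collapse, library
normalisation artifacts, or homoeolog expression bias other than complete
silencing. Tests passing on this generator therefore establish the
correctness of the statistics and the classification logic under the
stated model — not robustness to assembly artifacts in field data. One
visible consequence: with complete, error-free progenitor panels ~98% of
synthetic reads are taggable, whereas incomplete real panels tag far fewer.

## Coordinates and I/O conventions

Internally everything is 0-based, half-open; every emitted position is
1-based on the unpadded consensus. ACE pads (`*`), read gap characters and
N bases contribute zero depth (substitutions only; indels are out of
scope). ACE-complemented reads are already stored consensus-forward by the
assembler, so pileups never consult strand. The simulator's native TSV
alignment table is the primary pipeline path; ACE is a supported input
dialect. The read-length filter keeps reads of ≥ 100 bp and is idempotent.

## Sub-genome tagging

An 11-mer-seeded, ungapped-extension local aligner stands in for a
full external alignment tool: panel sequences are indexed by
non-overlapping 11-mers, every read k-mer (both strands) seeds a diagonal,
and the best matches-minus-mismatches segment on any seeded diagonal is the
panel score. Ties are exact integer ties — no tolerance band. The rule that
a read hitting only one panel stays `unknown` is deliberately conservative
(such a read is arguably assignable); `assign_single_hits=True` switches to
the permissive alternative. The minimum score of 30 is a package default —
roughly three error-free seed lengths — not an empirically fitted value.

## Digital gene expression

Counts are normalised per 10,000 reads of the library or group. The
default normaliser is reads-assembled-per-library (column sums of the
count table), since counts are contig-level; raw library totals can be
passed instead. Tag-stratified comparisons normalise by the total tagged
reads of the relevant tag class, because untagged reads carry no
information for A/D contrasts.

Significance of a pairwise comparison is the two-sided Fisher's exact test
on (contig reads vs remaining reads) × group; the differential flag
requires p < alpha (0.05) and normalised fold ≥ min_fold (2). "Greater
than 2-fold" is implemented as ≥ 2; an infinite fold (one-sided zeros)
passes the fold criterion; contigs with zero counts in both groups are
never flagged and have undefined fold. No multiple-testing correction is
applied by default, matching standard EST-count practice of the era;
Benjamini–Hochberg can be layered on the p column if desired.

The R statistic is computed as R = Σ_j x_j ln(x_j/(N_j f)), f = Σx/ΣN,
with zero-count terms contributing nothing; 2R is the deviance of the
multinomial likelihood-ratio comparison, and for more than two libraries
its p-value uses χ² with (libraries − 1) degrees of freedom.

**Known limit (deliberately red test).** The χ²₁ p-value of 2R and the
two-sided Fisher p do *not* agree within 0.02 merely because expected cell
counts reach 10: the exact conditional p differs from the asymptotic one by
a discreteness term of roughly half the conditional point mass at the
observed table, which at expected counts near 10 can reach ~0.15 for
near-balanced tables and decays only as the inverse square root of the
total count. The suite keeps a faithful test of the 0.02/≥10 claim, which
fails and documents the structure of the disagreement, alongside a passing
demonstration of the agreement at large expected counts. In the rejection
region (p ≤ 0.05) the two tests rarely differ materially.

## SNP calling and partition

A genotype's call at a position needs depth ≥ 6 (`min_depth`); it is
polymorphic when at least two alleles each reach 10% of that genotype's
depth (`maf`) **and** 2 reads (`min_minor`) — both thresholds apply.
Monomorphic calls take the majority allele; exact ties break
lexicographically and are logged. Positions with dual coverage (both
genotypes ≥ min_depth) are classified into cases A–D; those positions are
also the density denominator (eligible bases). Cases B/C do not require the
monomorphic genotype's allele to occur among the polymorphic genotype's
alleles; a boolean records whether it does. Multi-allelic positions count
once (positions, not alleles). Per-genotype intra scans run wherever that
genotype alone reaches the depth threshold.

## SSR mining and primers

Maximal perfect tandem repeats with per-unit-length minimum repeats
(10/6/5/5/5/5 for unit lengths 1–6); a run whose unit has a shorter period
is reported at the shortest unit. Overlapping runs resolve to the longer
span (tie: shorter unit). Qualifying p2–p6 runs separated by at most 100 bp
merge into compound records; mononucleotide runs are reported separately
and excluded from the p2–p6 totals (homopolymer runs are 454's known
weakness). Motif classes are the lexicographic minimum over cyclic
rotations of the motif and its reverse complement, rendered `X/revcomp(X)`.

Primer triplets: each forward primer is the 19 bases upstream of the SNP
plus its allele at the 3′ terminus; the base at −4 is replaced by a
transversion partner of the template base, a *different* one in each primer
(the two mismatches differ in base, not position). Tails of 15 and 5
bases give the 10-bp product-size difference; tail sequences and the
long-tail-to-first-allele assignment are package conventions. Which allele
received which tail, and the exact mismatch bases, are not identifiable
from the protocol being emulated and are declared, configurable choices.
Thermodynamic optimisation is out of scope; a GC% heuristic is logged.

## Experiment design in tests and the acceptance script

Problem sizes were chosen so the whole suite and the acceptance script run
in minutes on one CPU while keeping counting statistics informative:

* **Null calibration**: 1,000 genes, 20,000 reads/library, no planted DE —
  the flagged fraction at alpha = 0.05, fold ≥ 2 stays ≤ 5% (measured
  ~1–2%; the joint p-and-fold rule is conservative).
* **DE recovery**: 200 genes, 20,000 reads/library, 30% of copies at
  4-fold — ≥ 90% of planted genes flagged with the correct direction;
  misses are the low-expression tail of the lognormal.
* **SNP-class recovery**: 40 genes, 4,000 reads/library. This experiment
  disables differential expression: a 4-fold copy skews the within-genotype
  homoeolog read ratio to 5:2, and near the coverage threshold the minor
  copy can then fall below the 2-read/10% rule by sampling alone — an
  expression-level confound, not a property of the classifier. With
  balanced copies and error-free reads the partition matches planted truth
  exactly at every position with both genotypes at depth ≥ 12; with 0.5%
  read error, homoeo-vs-allelic precision stays ≥ 0.90 (measured ≥ 0.97).
  Conversely the DE-recovery experiment disables silencing.
* **Scanner equivalence**: the SSR scanner is checked record-for-record
  against an independent regex brute force on 100 random 10-kb sequences;
  Fisher's test against full hypergeometric enumeration on every 2×2 table
  with all margins ≤ 30.
* **Determinism**: identical configuration (including the seed) reproduces
  byte-identical FASTA, TSV and VCF outputs; the full default pipeline
  (200 genes, 80,000 reads, tagging on) completes in about a minute.

The acceptance script additionally recomputes the dataset-level table
identities (sequencing totals and the high-quality cut, unigene and
reads-per-contig arithmetic, the variant-partition totals and the
inter-genotypic density of one SNP per 108 bp, SSR type totals, the
cross-platform concordance percentage) from their published per-library
and per-class inputs, through the same report functions the pipeline uses
on synthetic data.
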