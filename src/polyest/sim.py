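"""Synthetic allotetraploid fiber transcriptome generator.

Each gene descends from a common ancestral transcript and exists as four
copies: two homoeologous sub-genome copies (A and D) in each of two
genotypes (Gh and Gb). Homoeo-substitutions separate the A and D copies and
are shared by both genotypes; allelic substitutions separate the genotypes
at one copy. The generator plants both classes at disjoint positions, can
silence one homoeo-copy per genotype, applies stage-differential expression
to a fraction of gene copies, and draws 454-like reads (truncated-normal
lengths, uniform substitution errors) per library. Because every read is
recorded with its placement on the gene's own coordinate system, assembly is
bypassed: each gene directly yields one contig alignment with the ancestral
sequence as consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ._dna import BASES, decode, encode
from .aio import (
    GENOTYPES,
    LIBRARIES,
    STAGES,
    ContigAlignment,
    Placement,
    TaggedRead,
    genotype_of_library,
    stage_of_library,
    write_alignment_tsv,
    write_fasta,
)

COPIES = ("A", "D")

#: probability that a silencing event hits opposite copies in both genotypes
#: (the pattern that yields fixed inter-genotypic differences, class case D)
_OPPOSITE_SILENCING_P = 0.3


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic transcriptome.

    Defaults follow the emulated four-library design: mean gene length
    1,100 bp, read length 353 +/- 40 bp, one homoeo-substitution per 80 bp
    and one allelic substitution per 108 bp of consensus, and 20,000 reads
    in each of the four genotype x stage libraries.
    """

    n_genes: int = 200
    gene_length_range: tuple[int, int] = (600, 1600)
    homoeo_divergence: float = 1 / 80
    allelic_divergence: float = 1 / 108
    silenced_fraction: float = 0.05
    de_fraction: float = 0.10
    de_fold: float = 4.0
    reads_per_library: int = 20_000
    read_length_mean: float = 353.0
    read_length_sd: float = 40.0
    read_error_rate: float = 0.005
    expression_sigma: float = 1.0
    ssr_fraction: float = 0.15  # genes carrying one planted microsatellite
    library_sizes: tuple[tuple[str, int], ...] | None = None  # overrides reads_per_library
    seed: int = 0

    def validate(self) -> None:
        for name in ("homoeo_divergence", "allelic_divergence", "silenced_fraction",
                     "de_fraction", "read_error_rate", "ssr_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.de_fold < 1:
            raise ValueError("de_fold must be >= 1")
        if self.reads_per_library <= 0:
            raise ValueError("reads_per_library must be positive")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        lo, hi = self.gene_length_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid gene_length_range")
        # expected planted variants per bp must stay clear of saturation,
        # otherwise the disjoint-class draw cannot succeed
        if self.homoeo_divergence + self.allelic_divergence > 1 / 3:
            raise ValueError(
                "homoeo_divergence + allelic_divergence too high: expected variants "
                "exceed one third of gene length"
            )

    def reads_for(self, library: str) -> int:
        if self.library_sizes is not None:
            return dict(self.library_sizes)[library]
        return self.reads_per_library


@dataclass
class GeneTruth:
    """Ground truth for one gene: sequences, planted variants, expression."""

    gene_id: str
    copy_a_base: str  # ancestral A-copy sequence (progenitor-A-like)
    copy_d_base: str  # A-copy plus homoeo substitutions (progenitor-D-like)
    seqs: dict[tuple[str, str], str]  # (copy, genotype) -> sequence
    homoeo_positions: list[int]  # 0-based
    allelic_positions: list[tuple[int, str, str]]  # (0-based pos, copy, genotype of origin)
    silenced: frozenset[tuple[str, str]]  # (genotype, copy)
    planted_ssr: tuple[int, str, int] | None  # (0-based start, motif, repeats)
    base_level: float
    de_copies: frozenset[str]
    de_up_stage: str  # stage favoured when a copy is differential

    @property
    def length(self) -> int:
        return len(self.copy_a_base)

    def expression(self, copy: str, genotype: str, stage: str, de_fold: float) -> float:
        if (genotype, copy) in self.silenced:
            return 0.0
        level = self.base_level
        if copy in self.de_copies and stage == self.de_up_stage:
            level *= de_fold
        return level

    def expressed_alleles(self, genotype: str, pos: int) -> set[str]:
        return {
            self.seqs[(c, genotype)][pos]
            for c in COPIES
            if (genotype, c) not in self.silenced
        }

    def expected_class(self, pos: int) -> str:
        """Observable variant class at a planted position (error-free, deep data)."""
        gh = self.expressed_alleles("Gh", pos)
        gb = self.expressed_alleles("Gb", pos)
        if not gh or not gb:
            return "none"
        poly_gh, poly_gb = len(gh) > 1, len(gb) > 1
        if poly_gh and poly_gb:
            return "caseA_homoeo"
        if poly_gh:
            return "caseB_Gh_poly"
        if poly_gb:
            return "caseC_Gb_poly"
        return "caseD_fixed_diff" if gh != gb else "none"


@dataclass
class SimTruth:
    """Full ground truth for a simulated transcriptome."""

    config: SimConfig
    genes: list[GeneTruth] = field(default_factory=list)

    def gene(self, gene_id: str) -> GeneTruth:
        return next(g for g in self.genes if g.gene_id == gene_id)

    def variant_classes(self) -> dict[tuple[str, int], str]:
        """(gene id, 1-based position) -> expected class for every planted variant."""
        out: dict[tuple[str, int], str] = {}
        for g in self.genes:
            for pos in g.homoeo_positions:
                out[(g.gene_id, pos + 1)] = g.expected_class(pos)
            for pos, _copy, _gt in g.allelic_positions:
                out[(g.gene_id, pos + 1)] = g.expected_class(pos)
        return out

    def progenitor_panels(self) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
        """Diploid-progenitor-like transcript panels (A-like, D-like)."""
        panel_a = [(f"{g.gene_id}_A", g.copy_a_base) for g in self.genes]
        panel_d = [(f"{g.gene_id}_D", g.copy_d_base) for g in self.genes]
        return panel_a, panel_d

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.genes:
            for pos in g.homoeo_positions:
                rows.append((g.gene_id, pos + 1, "homoeo", "", "", g.expected_class(pos)))
            for pos, copy, gt in g.allelic_positions:
                rows.append((g.gene_id, pos + 1, "allelic", copy, gt, g.expected_class(pos)))
        return pd.DataFrame(
            rows, columns=["gene", "pos", "planted", "copy", "genotype", "expected_class"]
        )


def _mutate(codes: np.ndarray, positions: np.ndarray, rng: np.random.Generator) -> None:
    """Uniform substitution over the three alternative bases, in place."""
    if len(positions) == 0:
        return
    shift = rng.integers(1, 4, size=len(positions))
    codes[positions] = (codes[positions] + shift) % 4


def simulate_transcriptome(config: SimConfig) -> SimTruth:
    """Plant homoeo and allelic substitutions on a common ancestor per gene.

    Homoeo and allelic positions are drawn jointly without replacement, so the
    two classes are disjoint by construction; variant counts per gene are
    binomial with per-bp rates `homoeo_divergence` and `allelic_divergence`
    (rates on the consensus coordinate, i.e. totals over both copies).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.gene_length_range
    truth = SimTruth(config=config)
    width = len(str(config.n_genes))
    # unit-length mix of planted microsatellites (di/tri repeats dominate
    # transcriptome SSRs); repeat counts start at the detection thresholds
    ssr_unit_p = {2: 0.36, 3: 0.56, 4: 0.03, 5: 0.01, 6: 0.04}
    ssr_min_rep = {2: 6, 3: 5, 4: 5, 5: 5, 6: 5}
    for gi in range(config.n_genes):
        L = int(rng.integers(lo, hi + 1))
        anc = rng.integers(0, 4, size=L).astype(np.uint8)
        planted_ssr = None
        if rng.random() < config.ssr_fraction:
            p = int(rng.choice(list(ssr_unit_p), p=list(ssr_unit_p.values())))
            unit = rng.integers(0, 4, size=p).astype(np.uint8)
            while any(p % d == 0 and np.array_equal(unit, np.tile(unit[:d], p // d))
                      for d in range(1, p)):
                unit = rng.integers(0, 4, size=p).astype(np.uint8)
            reps = int(ssr_min_rep[p] + rng.integers(0, 6))
            span = p * reps
            if L >= span + 120:  # keep 60-bp flanks; skip in very short genes
                start = int(rng.integers(60, L - 60 - span))
                anc[start : start + span] = np.tile(unit, reps)
                planted_ssr = (start, decode(unit), reps)
        n_h = rng.binomial(L, config.homoeo_divergence)
        n_a = rng.binomial(L, config.allelic_divergence)
        positions = rng.choice(L, size=min(n_h + n_a, L), replace=False)
        homoeo = np.sort(positions[:n_h])
        allelic = np.sort(positions[n_h:])

        copy_a = anc.copy()
        copy_d = anc.copy()
        _mutate(copy_d, homoeo, rng)

        seqs = {
            ("A", "Gh"): copy_a.copy(), ("A", "Gb"): copy_a.copy(),
            ("D", "Gh"): copy_d.copy(), ("D", "Gb"): copy_d.copy(),
        }
        allelic_records = []
        for pos in allelic:
            copy = COPIES[int(rng.integers(2))]
            genotype = GENOTYPES[int(rng.integers(2))]
            _mutate(seqs[(copy, genotype)], np.array([pos]), rng)
            allelic_records.append((int(pos), copy, genotype))

        silenced: frozenset[tuple[str, str]] = frozenset()
        if rng.random() < config.silenced_fraction:
            if rng.random() < _OPPOSITE_SILENCING_P:
                c = COPIES[int(rng.integers(2))]
                other = COPIES[1 - COPIES.index(c)]
                silenced = frozenset({("Gh", c), ("Gb", other)})
            else:
                silenced = frozenset(
                    {(GENOTYPES[int(rng.integers(2))], COPIES[int(rng.integers(2))])}
                )

        base_level = float(rng.lognormal(mean=0.0, sigma=config.expression_sigma))
        de_copies = frozenset(c for c in COPIES if rng.random() < config.de_fraction)
        de_up_stage = STAGES[int(rng.integers(2))]

        truth.genes.append(
            GeneTruth(
                gene_id=f"gene{gi:0{width}d}",
                copy_a_base=decode(copy_a),
                copy_d_base=decode(copy_d),
                seqs={k: decode(v) for k, v in seqs.items()},
                homoeo_positions=[int(p) for p in homoeo],
                allelic_positions=allelic_records,
                silenced=silenced,
                planted_ssr=planted_ssr,
                base_level=base_level,
                de_copies=de_copies,
                de_up_stage=de_up_stage,
            )
        )
    return truth


@dataclass
class SimReadSet:
    """Simulated reads plus their truth placements and per-gene alignments."""

    reads_by_library: dict[str, list[TaggedRead]]
    alignments: list[ContigAlignment]
    read_truth: pd.DataFrame  # read_id, library, gene, copy, genotype, stage, start, length

    def all_reads(self) -> list[TaggedRead]:
        return [r for lib in LIBRARIES for r in self.reads_by_library[lib]]

    def read_library_map(self) -> dict[str, str]:
        return {r.id: r.library for r in self.all_reads()}

    def true_tag_map(self) -> dict[str, str]:
        return dict(zip(self.read_truth["read_id"], self.read_truth["copy"]))


def _copy_weights(truth: SimTruth, library: str) -> np.ndarray:
    cfg = truth.config
    gt, stage = genotype_of_library(library), stage_of_library(library)
    return np.array(
        [g.expression(c, gt, stage, cfg.de_fold) for g in truth.genes for c in COPIES]
    )


def simulate_reads(truth: SimTruth, config: SimConfig | None = None) -> SimReadSet:
    """Draw 454-like reads per library and assemble truth alignments.

    Read counts per (gene, copy) are multinomial with weights proportional to
    expression; lengths are truncated-normal (resampled until >= 1 bp, capped
    at gene length); errors are uniform substitutions. Each read's placement
    on its gene's ancestral coordinates yields one contig alignment per gene.
    """
    cfg = config or truth.config
    rng = np.random.default_rng(cfg.seed + 1)
    reads_by_library: dict[str, list[TaggedRead]] = {lib: [] for lib in LIBRARIES}
    placements: dict[str, list[Placement]] = {g.gene_id: [] for g in truth.genes}
    rows = []
    units = [(g, c) for g in truth.genes for c in COPIES]
    for lib in LIBRARIES:
        weights = _copy_weights(truth, lib)
        total = weights.sum()
        if total == 0:
            continue
        counts = rng.multinomial(cfg.reads_for(lib), weights / total)
        for (gene, copy), n in zip(units, counts):
            if n == 0:
                continue
            L = gene.length
            gt, stage = genotype_of_library(lib), stage_of_library(lib)
            src = encode(gene.seqs[(copy, gt)])
            lengths = np.rint(rng.normal(cfg.read_length_mean, cfg.read_length_sd, size=n))
            while np.any(lengths < 1):  # truncated normal: resample until >= 1 bp
                bad = lengths < 1
                lengths[bad] = np.rint(
                    rng.normal(cfg.read_length_mean, cfg.read_length_sd, size=bad.sum())
                )
            lengths = np.minimum(lengths.astype(np.int64), L)
            for i in range(n):
                rl = int(lengths[i])
                start = int(rng.integers(0, L - rl + 1))
                seq = src[start : start + rl].copy()
                n_err = rng.binomial(rl, cfg.read_error_rate)
                if n_err:
                    _mutate(seq, rng.choice(rl, size=n_err, replace=False), rng)
                rid = f"{lib}:{gene.gene_id}:{copy}:{i:05d}"
                s = decode(seq)
                reads_by_library[lib].append(TaggedRead(rid, s, lib))
                placements[gene.gene_id].append(Placement(rid, start, "+", s))
                rows.append((rid, lib, gene.gene_id, copy, gt, stage, start + 1, rl))
    alignments = [
        ContigAlignment(g.gene_id, g.copy_a_base, placements[g.gene_id]) for g in truth.genes
    ]
    read_truth = pd.DataFrame(
        rows,
        columns=["read_id", "library", "gene", "copy", "genotype", "stage", "start", "length"],
    )
    return SimReadSet(reads_by_library, alignments, read_truth)


def simulate_counts(truth: SimTruth, config: SimConfig | None = None) -> pd.DataFrame:
    """Gene x library read-count table drawn directly (no sequences).

    Fast path for expression-level experiments: the same multinomial model as
    :func:`simulate_reads` without generating read sequences.
    """
    cfg = config or truth.config
    rng = np.random.default_rng(cfg.seed + 1)
    idx = [g.gene_id for g in truth.genes]
    out = pd.DataFrame(0, index=idx, columns=list(LIBRARIES), dtype=np.int64)
    for lib in LIBRARIES:
        weights = _copy_weights(truth, lib)
        total = weights.sum()
        if total == 0:
            continue
        counts = rng.multinomial(cfg.reads_for(lib), weights / total)
        out[lib] = counts.reshape(len(idx), len(COPIES)).sum(axis=1)
    return out


def write_dataset(truth: SimTruth, readset: SimReadSet, outdir: str | Path) -> None:
    """Write the library FASTAs, progenitor panels, truth tables and alignments."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for lib in LIBRARIES:
        write_fasta(
            [(r.id, r.sequence) for r in readset.reads_by_library[lib]],
            outdir / f"reads_{lib}.fasta",
        )
    panel_a, panel_d = truth.progenitor_panels()
    write_fasta(panel_a, outdir / "panel_A.fasta")
    write_fasta(panel_d, outdir / "panel_D.fasta")
    truth.truth_frame().to_csv(outdir / "variant_truth.tsv", sep="\t", index=False)
    readset.read_truth.to_csv(outdir / "read_truth.tsv", sep="\t", index=False)
    write_alignment_tsv(readset.alignments, outdir / "alignments.tsv")
    write_fasta(
        [(a.contig_id, a.unpadded_consensus) for a in readset.alignments],
        outdir / "consensus.fasta",
    )
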