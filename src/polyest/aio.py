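"""Alignment and sequence I/O: FASTA, ACE, read filtering and pileups.

The four sequencing libraries combine two genotypes (Gh = G. hirsutum-like,
Gb = G. barbadense-like) and two fiber stages (10 and 22 days post anthesis).
Contig alignments carry a padded consensus (pads written ``*``); all reported
positions are 1-based on the *unpadded* consensus, while everything internal
is 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Sequencing import Ace

from ._dna import BASES, encode

logger = logging.getLogger(__name__)

LIBRARIES = ("Gh10", "Gb10", "Gh22", "Gb22")
GENOTYPES = ("Gh", "Gb")
STAGES = ("10", "22")
TAGS = ("A", "D", "unknown")


def genotype_of_library(library: str) -> str:
    return library[:2]


def stage_of_library(library: str) -> str:
    return library[2:]


class FastaError(ValueError):
    """Malformed FASTA content."""


class EmptyFastaError(FastaError):
    """FASTA file contained no records."""


@dataclass
class TaggedRead:
    """One sequenced read with its library membership and sub-genome tag."""

    id: str
    sequence: str
    library: str
    tag: str = "unknown"

    def __post_init__(self) -> None:
        if self.library not in LIBRARIES:
            raise ValueError(f"unknown library {self.library!r} for read {self.id}")
        if self.tag not in TAGS:
            raise ValueError(f"unknown tag {self.tag!r} for read {self.id}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Placement:
    """A read placed on a padded contig consensus, consensus-forward."""

    read_id: str
    start: int  # 0-based column on the padded consensus
    strand: str  # '+' or '-'; '-' reads are already stored reverse-complemented
    gapped_seq: str  # over {A,C,G,T,N,*}


@dataclass
class ContigAlignment:
    """A contig consensus with its placed reads (the pileup source)."""

    contig_id: str
    consensus: str  # padded, over {A,C,G,T,N,*}
    placements: list[Placement] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._unpad_map: np.ndarray | None = None

    @property
    def padded_length(self) -> int:
        return len(self.consensus)

    @property
    def unpadded_consensus(self) -> str:
        return self.consensus.replace("*", "")

    @property
    def unpadded_length(self) -> int:
        return self.padded_length - self.consensus.count("*")

    def padded_to_unpadded(self) -> np.ndarray:
        """Map padded column -> 0-based unpadded position, -1 at pad columns."""
        if self._unpad_map is None:
            is_pad = np.frombuffer(self.consensus.encode("ascii"), dtype=np.uint8) == ord("*")
            m = np.cumsum(~is_pad) - 1
            m[is_pad] = -1
            self._unpad_map = m.astype(np.int64)
        return self._unpad_map


@dataclass
class PositionCounts:
    """Stratified allele depths for one unpadded consensus position."""

    contig_id: str
    position: int  # 1-based on the unpadded consensus
    by_genotype: dict[str, dict[str, int]]
    by_tag: dict[str, dict[str, int]]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file; sequences are upper-cased on read.

    Raises :class:`EmptyFastaError` for an empty file and :class:`FastaError`
    for malformed content (text before the first header, blank record ids).
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise EmptyFastaError(f"{path} contains no FASTA records")
    if not text.lstrip().startswith(">"):
        raise FastaError(f"{path}: content before the first '>' header")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FastaError(f"{path}: record with empty header")
        rec.seq = Seq(str(rec.seq).upper())
        records.append(rec)
    if not records:
        raise EmptyFastaError(f"{path} contains no FASTA records")
    return records


def write_fasta(records: Iterable[SeqRecord | tuple[str, str]], path: str | Path) -> None:
    """Write records (SeqRecord or (id, sequence) pairs) as FASTA."""
    recs = []
    for rec in records:
        if isinstance(rec, SeqRecord):
            recs.append(rec)
        else:
            rid, seq = rec
            recs.append(SeqRecord(Seq(seq), id=rid, description=""))
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta-2line")


# ---------------------------------------------------------------------------
# ACE and the simulator's native alignment table
# ---------------------------------------------------------------------------

def read_ace(path: str | Path) -> list[ContigAlignment]:
    """Parse an ACE assembly (consed dialect: AS/CO/AF/RD; BQ ignored).

    Complemented reads are stored reverse-complemented by the assembler, so
    every placement is consensus-forward already; only the strand flag is kept.
    """
    path = Path(path)
    if not path.read_text().strip():
        return []
    try:
        ace = Ace.read(open(path))
    except Exception as exc:  # truncated / malformed records
        raise FastaError(f"{path}: failed to parse ACE file: {exc}") from exc
    alignments = []
    for contig in ace.contigs:
        starts = {af.name: af.padded_start for af in contig.af}
        strands = {af.name: ("-" if af.coru == "C" else "+") for af in contig.af}
        aln = ContigAlignment(contig_id=contig.name, consensus=contig.sequence.upper())
        for rd in contig.reads:
            name = rd.rd.name
            if name not in starts:
                raise FastaError(
                    f"{path}: contig {contig.name}: RD {name} without an AF record"
                )
            aln.placements.append(
                Placement(
                    read_id=name,
                    start=starts[name] - 1,  # AF is 1-based
                    strand=strands[name],
                    gapped_seq=rd.rd.sequence.upper(),
                )
            )
        alignments.append(aln)
    return alignments


_ALN_COLUMNS = ["contig", "read_id", "start", "strand", "gapped_read"]


def write_alignment_tsv(alignments: Iterable[ContigAlignment], path: str | Path) -> None:
    """Write alignments as TSV: contig, read id, start (1-based, padded), strand, gapped read."""
    rows = []
    for aln in alignments:
        for p in aln.placements:
            rows.append((aln.contig_id, p.read_id, p.start + 1, p.strand, p.gapped_seq))
    pd.DataFrame(rows, columns=_ALN_COLUMNS).to_csv(path, sep="\t", index=False)


def read_alignment_tsv(path: str | Path, consensus: Mapping[str, str]) -> list[ContigAlignment]:
    """Read the native alignment table back; `consensus` maps contig id -> padded consensus."""
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "read_id": str})
    alignments = []
    for contig_id, grp in df.groupby("contig", sort=True):
        aln = ContigAlignment(contig_id=str(contig_id), consensus=consensus[str(contig_id)])
        for row in grp.itertuples(index=False):
            aln.placements.append(
                Placement(row.read_id, int(row.start) - 1, row.strand, row.gapped_read)
            )
        alignments.append(aln)
    return alignments


# ---------------------------------------------------------------------------
# Read-length filter
# ---------------------------------------------------------------------------

def trim_filter_reads(
    reads: Sequence[TaggedRead], min_len: int = 100
) -> tuple[list[TaggedRead], list[TaggedRead], pd.DataFrame]:
    """Discard reads shorter than `min_len` bp; report per-library statistics.

    Returns (kept, discarded, summary). The summary carries, per library,
    the trimmed-read total, base count, mean length, the number of short
    reads and the resulting high-quality count.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept = [r for r in reads if len(r) >= min_len]
    discarded = [r for r in reads if len(r) < min_len]
    rows = []
    for lib in LIBRARIES:
        lib_reads = [r for r in reads if r.library == lib]
        n = len(lib_reads)
        bases = sum(len(r) for r in lib_reads)
        short = sum(1 for r in lib_reads if len(r) < min_len)
        rows.append(
            {
                "library": lib,
                "n_reads": n,
                "n_bases": bases,
                "mean_length": round(bases / n, 1) if n else 0.0,
                "n_short": short,
                "n_high_quality": n - short,
            }
        )
    summary = pd.DataFrame(rows).set_index("library")
    return kept, discarded, summary


# ---------------------------------------------------------------------------
# Pileups
# ---------------------------------------------------------------------------

class Pileup:
    """Per-position allele depths for one contig, stratified by genotype and tag.

    Depths are held as integer arrays of shape (stratum, unpadded length, 4)
    over the base order A,C,G,T. Pad columns, read gap characters and N bases
    contribute zero depth.
    """

    def __init__(self, contig_id: str, length: int, consensus: str) -> None:
        self.contig_id = contig_id
        self.length = length
        self.consensus = consensus  # unpadded
        self.by_genotype = np.zeros((len(GENOTYPES), length, 4), dtype=np.int32)
        self.by_tag = np.zeros((len(TAGS), length, 4), dtype=np.int32)

    def genotype_depth(self, genotype: str) -> np.ndarray:
        return self.by_genotype[GENOTYPES.index(genotype)].sum(axis=1)

    def counts_at(self, position: int) -> PositionCounts:
        """Allele depths at a 1-based unpadded position."""
        i = position - 1
        if not 0 <= i < self.length:
            raise IndexError(f"position {position} outside contig {self.contig_id}")
        by_gt = {
            g: {BASES[b]: int(c) for b, c in enumerate(self.by_genotype[gi, i]) if c}
            for gi, g in enumerate(GENOTYPES)
        }
        by_tag = {
            t: {BASES[b]: int(c) for b, c in enumerate(self.by_tag[ti, i]) if c}
            for ti, t in enumerate(TAGS)
        }
        return PositionCounts(self.contig_id, position, by_gt, by_tag)

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: contig, pos, genotype, allele, depth."""
        rows = []
        for gi, g in enumerate(GENOTYPES):
            pos, base = np.nonzero(self.by_genotype[gi])
            for p, b in zip(pos, base):
                rows.append((self.contig_id, int(p) + 1, g, BASES[b], int(self.by_genotype[gi, p, b])))
        return pd.DataFrame(rows, columns=["contig", "pos", "genotype", "allele", "depth"])


def build_pileup(
    alignment: ContigAlignment,
    read_library: Mapping[str, str],
    read_tag: Mapping[str, str] | None = None,
) -> Pileup:
    """Accumulate stratified allele depths over the unpadded consensus.

    Every placed read must appear in `read_library`; `read_tag` may omit reads
    (treated as unknown). Bases aligned to pad columns, gap characters in the
    read and N bases are non-calls and add no depth.
    """
    unpad = alignment.padded_to_unpadded()
    pile = Pileup(alignment.contig_id, alignment.unpadded_length, alignment.unpadded_consensus)
    for p in alignment.placements:
        if p.read_id not in read_library:
            raise KeyError(
                f"read {p.read_id} placed on {alignment.contig_id} has no library assignment"
            )
        gi = GENOTYPES.index(genotype_of_library(read_library[p.read_id]))
        tag = read_tag.get(p.read_id, "unknown") if read_tag is not None else "unknown"
        ti = TAGS.index(tag)
        codes = encode(p.gapped_seq)
        cols = p.start + np.arange(len(codes))
        inside = (cols >= 0) & (cols < alignment.padded_length)
        ucols = np.full(len(codes), -1, dtype=np.int64)
        ucols[inside] = unpad[cols[inside]]
        valid = (codes != 255) & (ucols >= 0)
        np.add.at(pile.by_genotype[gi], (ucols[valid], codes[valid].astype(np.int64)), 1)
        np.add.at(pile.by_tag[ti], (ucols[valid], codes[valid].astype(np.int64)), 1)
    return pile
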