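"""Microsatellite (SSR) mining and allele-specific primer construction.

SSR detection follows MISA conventions: maximal perfect tandem repeats,
motif classes canonicalised over cyclic rotations and reverse complements,
shorter-unit priority for degenerate units (``ATATAT`` is a dinucleotide
run, never a hexanucleotide one), and merging of qualifying repeats within
a bounded interruption into compound records. Mononucleotide runs are
detected but kept apart from the p2-p6 totals.

Allele-specific SNP genotyping primers come as triplets: two forward primers
ending on the alternative alleles, tailed with 15 and 5 extra bases so the
two products differ by 10 bp, each with a destabilizing mismatch four bases
from the 3' end; and one common reverse primer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from ._dna import revcomp, transversion_partners
from .snp import VariantCall

DEFAULT_MIN_REPEATS = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}

#: fixed primer tails producing the 10-bp product-size difference
LONG_TAIL = "CACGACGTTGTAAAA"  # 15 bases
SHORT_TAIL = "CACGA"  # 5 bases


def canonical_motif(motif: str) -> str:
    """Lexicographically smallest cyclic rotation of the motif or its
    reverse complement (the class representative)."""
    if not 1 <= len(motif) <= 6:
        raise ValueError("motif length must be 1-6")
    if any(b not in "ACGT" for b in motif):
        raise ValueError(f"motif {motif!r} contains non-ACGT bases")
    rc = revcomp(motif)
    rotations = {motif[i:] + motif[:i] for i in range(len(motif))}
    rotations |= {rc[i:] + rc[:i] for i in range(len(rc))}
    return min(rotations)


def motif_class(motif: str) -> str:
    """Class label rendered ``X/revcomp(X)`` (just ``X`` when the reverse
    complement already lies in X's rotation orbit, e.g. AT)."""
    canon = canonical_motif(motif)
    rc = revcomp(canon)
    if rc in {canon[i:] + canon[:i] for i in range(len(canon))}:
        return canon
    return f"{canon}/{rc}"


def _primitive(unit: str) -> bool:
    p = len(unit)
    return not any(p % d == 0 and unit == unit[:d] * (p // d) for d in range(1, p))


@dataclass
class SSRRecord:
    """One simple or compound microsatellite on a contig sequence."""

    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    motif: str  # as found; "compound" for compound records
    unit_length: int  # 0 for compound records
    repeat_count: int  # 0 for compound records
    compound: bool = False
    members: list["SSRRecord"] = field(default_factory=list)
    contig_id: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def ssr_class(self) -> str:
        return "compound" if self.compound else motif_class(self.motif)

    @property
    def ssr_type(self) -> str:
        return "compound" if self.compound else f"p{self.unit_length}"


def _find_simple(seq: str, min_repeats: Mapping[int, int]) -> list[SSRRecord]:
    L = len(seq)
    records = []
    for p, min_rep in sorted(min_repeats.items()):
        i = 0
        while i + p * min_rep <= L:
            unit = seq[i : i + p]
            if any(b not in "ACGT" for b in unit) or not _primitive(unit):
                i += 1
                continue
            t = i + p
            while t < L and seq[t] == seq[t - p] and seq[t] in "ACGT":
                t += 1
            reps = (t - i) // p
            if reps >= min_rep:
                records.append(
                    SSRRecord(start=i + 1, end=i + p * reps, motif=unit,
                              unit_length=p, repeat_count=reps)
                )
                i += p * reps
            else:
                i += 1
    return records


def _resolve_overlaps(records: list[SSRRecord]) -> list[SSRRecord]:
    """Keep the longer span when two runs overlap (tie: shorter unit)."""
    kept: list[SSRRecord] = []
    for rec in sorted(records, key=lambda r: (-r.length, r.unit_length, r.start)):
        if all(rec.end < k.start or rec.start > k.end for k in kept):
            kept.append(rec)
    return sorted(kept, key=lambda r: r.start)


def find_ssrs(
    seq: str,
    min_repeats: Mapping[int, int] | None = None,
    max_interruption: int = 100,
    contig_id: str = "",
) -> list[SSRRecord]:
    """MISA-style SSR scan of one sequence.

    Simple records are maximal perfect runs meeting the per-unit-length
    repeat thresholds; qualifying p2-p6 records separated by at most
    `max_interruption` bases merge into one compound record (mononucleotide
    runs stay simple and never join compounds).
    """
    seq = seq.upper()
    mins = dict(DEFAULT_MIN_REPEATS if min_repeats is None else min_repeats)
    simple = _resolve_overlaps(_find_simple(seq, mins))
    mono = [r for r in simple if r.unit_length == 1]
    poly = [r for r in simple if r.unit_length >= 2]

    out: list[SSRRecord] = list(mono)
    group: list[SSRRecord] = []
    for rec in poly:
        if group and rec.start - group[-1].end - 1 <= max_interruption:
            group.append(rec)
        else:
            out.extend(_emit(group))
            group = [rec]
    out.extend(_emit(group))
    for r in out:
        r.contig_id = contig_id
        for m in r.members:
            m.contig_id = contig_id
    return sorted(out, key=lambda r: r.start)


def _emit(group: list[SSRRecord]) -> list[SSRRecord]:
    if not group:
        return []
    if len(group) == 1:
        return group
    return [
        SSRRecord(
            start=group[0].start,
            end=group[-1].end,
            motif="compound",
            unit_length=0,
            repeat_count=0,
            compound=True,
            members=list(group),
        )
    ]


def ssr_summary(records: Sequence[SSRRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-type counts and within-type canonical-class frequencies.

    Mononucleotide runs are tallied under ``p1`` but excluded from the
    grand total, which covers p2-p6 and compound records.
    """
    types = [f"p{p}" for p in range(1, 7)] + ["compound"]
    counts = {t: 0 for t in types}
    class_rows = []
    for rec in records:
        counts[rec.ssr_type] += 1
        if not rec.compound:
            class_rows.append((rec.ssr_type, rec.ssr_class))
    total = sum(v for t, v in counts.items() if t != "p1")
    type_table = pd.DataFrame(
        [{"ssr_type": t, "count": counts[t]} for t in types]
        + [{"ssr_type": "total_p2_to_compound", "count": total}]
    )
    if class_rows:
        cls = pd.DataFrame(class_rows, columns=["ssr_type", "ssr_class"])
        freq = (
            cls.groupby(["ssr_type", "ssr_class"]).size().rename("count").reset_index()
        )
        freq["pct_within_type"] = freq.groupby("ssr_type")["count"].transform(
            lambda s: (100 * s / s.sum()).round(0)
        )
    else:
        freq = pd.DataFrame(columns=["ssr_type", "ssr_class", "count", "pct_within_type"])
    return type_table, freq


def filter_design_candidates(
    records: Sequence[SSRRecord],
    seq_length: int,
    min_flank: int = 50,
) -> list[SSRRecord]:
    """Keep SSRs with at least `min_flank` non-repeat bases on both sides
    (repeats near contig ends cannot anchor primers)."""
    if min_flank < 1:
        raise ValueError("min_flank must be >= 1")
    return [
        r for r in records
        if r.start - 1 >= min_flank and seq_length - r.end >= min_flank
    ]


def records_frame(records: Sequence[SSRRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "contig": r.contig_id,
                "ssr_type": r.ssr_type,
                "motif": r.motif if not r.compound
                else ";".join(m.motif for m in r.members),
                "ssr_class": r.ssr_class if not r.compound else "compound",
                "repeats": r.repeat_count,
                "start": r.start,
                "end": r.end,
            }
        )
    return pd.DataFrame(
        rows, columns=["contig", "ssr_type", "motif", "ssr_class", "repeats", "start", "end"]
    )


# ---------------------------------------------------------------------------
# Allele-specific primer triplets
# ---------------------------------------------------------------------------

@dataclass
class PrimerTriplet:
    """Two tailed allele-specific forward primers plus a common reverse."""

    snp_id: str
    allele1: str
    allele2: str
    forward1: str  # long tail (15 bases), 3' terminus = allele1
    forward2: str  # short tail (5 bases), 3' terminus = allele2
    reverse: str
    mismatch_base1: str  # substituted base at position -4 of forward1
    mismatch_base2: str
    template_base: str  # original base at the -4 position
    product_size1: int
    product_size2: int

    @property
    def size_difference(self) -> int:
        return abs(self.product_size1 - self.product_size2)


def gc_percent(primer: str) -> float:
    """GC content heuristic used for logging primer quality."""
    return round(100 * sum(1 for b in primer if b in "GC") / len(primer), 1)


def design_snp_triplet(
    call: VariantCall,
    consensus: str,
    primer_len: int = 20,
    tails: tuple[str, str] = (LONG_TAIL, SHORT_TAIL),
    reverse_gap: int = 60,
) -> PrimerTriplet:
    """Build the allele-specific triplet for a biallelic inter-genotypic SNP.

    Each forward primer covers the `primer_len` - 1 bases upstream of the SNP
    plus its target allele at the 3' terminus, carries a destabilizing
    transversion of the template base four bases from the 3' end (a different
    substitution in each primer), and is tailed so the two PCR products
    differ by exactly ``len(tails[0]) - len(tails[1])`` bp (10 by default).
    The common reverse primer is the reverse complement of a window starting
    `reverse_gap` bases downstream of the SNP.
    """
    alleles = call.alleles
    if len(alleles) != 2:
        raise ValueError(f"{call.contig_id}:{call.position}: need a biallelic SNP")
    i = call.position - 1
    if i < primer_len - 1:
        raise ValueError(
            f"{call.contig_id}:{call.position}: insufficient upstream flank "
            f"({i} bp, need {primer_len - 1})"
        )
    rev_start = i + 1 + reverse_gap
    if rev_start + primer_len > len(consensus):
        raise ValueError(
            f"{call.contig_id}:{call.position}: insufficient downstream flank "
            f"for the reverse primer footprint"
        )
    upstream = consensus[i - (primer_len - 1) : i]
    template_base = upstream[-3]  # position -4 once the allele terminates the core
    m1, m2 = transversion_partners(template_base)
    core1 = upstream[:-3] + m1 + upstream[-2:] + alleles[0]
    core2 = upstream[:-3] + m2 + upstream[-2:] + alleles[1]
    reverse = revcomp(consensus[rev_start : rev_start + primer_len])
    core_product = (rev_start + primer_len) - (i - (primer_len - 1))
    return PrimerTriplet(
        snp_id=f"{call.contig_id}_{call.position}",
        allele1=alleles[0],
        allele2=alleles[1],
        forward1=tails[0] + core1,
        forward2=tails[1] + core2,
        reverse=reverse,
        mismatch_base1=m1,
        mismatch_base2=m2,
        template_base=template_base,
        product_size1=len(tails[0]) + core_product,
        product_size2=len(tails[1]) + core_product,
    )


def triplets_frame(triplets: Sequence[PrimerTriplet]) -> pd.DataFrame:
    rows = []
    for t in triplets:
        rows.append(
            {
                "snp_id": t.snp_id,
                "alleles": f"{t.allele1}/{t.allele2}",
                "forward_long": t.forward1,
                "forward_short": t.forward2,
                "reverse": t.reverse,
                "product_size_long": t.product_size1,
                "product_size_short": t.product_size2,
                "gc_forward_long": gc_percent(t.forward1),
                "gc_forward_short": gc_percent(t.forward2),
                "gc_reverse": gc_percent(t.reverse),
            }
        )
    return pd.DataFrame(rows)
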