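"""Variant mining from stratified pileups and the homoeo/allelic partition.

A genotype is polymorphic at a position when its depth reaches `min_depth`
and at least two alleles each reach the minor-allele thresholds (fraction
`maf` of that genotype's depth and an absolute minimum of `min_minor`
reads). Positions covered by both genotypes at `min_depth` are partitioned:

* case A - both genotypes polymorphic: a fixed difference between the
  co-assembled sub-genome copies (homoeo-SNP), not a genetic marker;
* case B / case C - exactly one genotype (Gh / Gb) polymorphic: an allelic,
  inter-genotypic SNP;
* case D - both genotypes monomorphic for different alleles: a fixed
  inter-genotypic difference, interpreted as each genotype expressing only
  one sub-genome copy.

Only base substitutions are considered (gaps and N add no depth upstream).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._dna import BASES, is_transition
from .aio import GENOTYPES, Pileup, PositionCounts

logger = logging.getLogger(__name__)

CASES = ("caseA_homoeo", "caseB_Gh_poly", "caseC_Gb_poly", "caseD_fixed_diff")


@dataclass(frozen=True)
class CallParams:
    min_depth: int = 6
    maf: float = 0.10
    min_minor: int = 2


@dataclass
class VariantCall:
    """A classified variant position on the unpadded consensus (1-based)."""

    contig_id: str
    position: int
    depths: dict[str, dict[str, int]]  # genotype -> allele -> depth
    called: dict[str, tuple[str, ...]]  # genotype -> called alleles
    classification: str  # one of CASES or "none"
    biallelic: bool
    substitution: str  # transition | transversion | multi
    mono_matches_poly: bool | None = None  # case B/C only

    @property
    def alleles(self) -> tuple[str, ...]:
        return tuple(sorted(set(a for al in self.called.values() for a in al)))


def call_intra_genotype(
    counts: Mapping[str, int],
    min_depth: int = 6,
    maf: float = 0.10,
    min_minor: int = 2,
) -> tuple[bool, bool, tuple[str, ...]]:
    """Intra-genotype call from one genotype's allele depths at a position.

    Returns (assessable, polymorphic, called alleles). Not assessable below
    `min_depth`; polymorphic when at least two alleles each reach both the
    `maf` fraction of the genotype's depth and `min_minor` reads; otherwise
    the call is the majority allele (ties broken lexicographically, logged).
    """
    depth = sum(counts.values())
    if depth < min_depth:
        return False, False, ()
    qualified = sorted(
        a for a, c in counts.items() if c >= min_minor and c >= maf * depth
    )
    if len(qualified) >= 2:
        return True, True, tuple(qualified)
    top = max(counts.values())
    majors = sorted(a for a, c in counts.items() if c == top)
    if len(majors) > 1:
        logger.info("majority-allele tie %s broken lexicographically", majors)
    return True, False, (majors[0],)


def ts_tv(alleles: Sequence[str]) -> str:
    """Substitution class of a called allele set."""
    uniq = sorted(set(alleles))
    if len(uniq) < 2:
        raise ValueError("substitution type needs at least 2 alleles")
    if len(uniq) > 2:
        return "multi"
    return "transition" if is_transition(uniq[0], uniq[1]) else "transversion"


def classify_position(
    pos: PositionCounts,
    min_depth: int = 6,
    maf: float = 0.10,
    min_minor: int = 2,
) -> VariantCall | None:
    """Partition one dual-coverage position; None when either genotype lacks
    `min_depth` (the position is then not classified nor counted as eligible)."""
    calls = {}
    for g in GENOTYPES:
        counts = pos.by_genotype.get(g, {})
        assessable, poly, alleles = call_intra_genotype(counts, min_depth, maf, min_minor)
        if not assessable:
            return None
        calls[g] = (poly, alleles)
    poly_gh, al_gh = calls["Gh"]
    poly_gb, al_gb = calls["Gb"]
    mono_matches = None
    if poly_gh and poly_gb:
        cls = "caseA_homoeo"
    elif poly_gh or poly_gb:
        cls = "caseB_Gh_poly" if poly_gh else "caseC_Gb_poly"
        poly_set, mono = (al_gh, al_gb) if poly_gh else (al_gb, al_gh)
        mono_matches = mono[0] in poly_set
    elif al_gh != al_gb:
        cls = "caseD_fixed_diff"
    else:
        cls = "none"
    alleles = tuple(sorted(set(al_gh) | set(al_gb)))
    return VariantCall(
        contig_id=pos.contig_id,
        position=pos.position,
        depths={g: dict(pos.by_genotype.get(g, {})) for g in GENOTYPES},
        called={"Gh": al_gh, "Gb": al_gb},
        classification=cls,
        biallelic=len(alleles) == 2,
        substitution=ts_tv(alleles) if len(alleles) >= 2 else "none",
        mono_matches_poly=mono_matches,
    )


@dataclass
class ContigScan:
    """All variant evidence for one contig."""

    contig_id: str
    calls: list[VariantCall]  # classified dual-coverage variant positions
    eligible_bases: int  # positions with both genotypes at min_depth
    assessable_bases: dict[str, int]  # per genotype, positions at min_depth
    intra: dict[str, list[tuple[int, tuple[str, ...]]]]  # per-genotype SNPs


def scan_contig(pileup: Pileup, params: CallParams = CallParams()) -> ContigScan:
    """Classify every dual-coverage position of a contig and run the
    per-genotype intra scans (a contig is intra-eligible for a genotype
    wherever that genotype alone reaches the depth threshold)."""
    md, maf, mm = params.min_depth, params.maf, params.min_minor
    counts = pileup.by_genotype  # (genotype, L, 4)
    depth = counts.sum(axis=2)
    ok = depth >= md
    eligible = ok.all(axis=0)
    qual = (counts >= mm) & (counts >= maf * depth[..., None])
    poly = ok & (qual.sum(axis=2) >= 2)
    major = counts.argmax(axis=2)  # ties -> lowest index = lexicographic

    intra: dict[str, list[tuple[int, tuple[str, ...]]]] = {g: [] for g in GENOTYPES}
    for gi, g in enumerate(GENOTYPES):
        for i in np.nonzero(poly[gi])[0]:
            _, _, alleles = call_intra_genotype(
                {BASES[b]: int(c) for b, c in enumerate(counts[gi, i]) if c}, md, maf, mm
            )
            intra[g].append((int(i) + 1, alleles))

    candidate = eligible & (poly.any(axis=0) | (major[0] != major[1]))
    calls = []
    for i in np.nonzero(candidate)[0]:
        call = classify_position(pileup.counts_at(int(i) + 1), md, maf, mm)
        if call is not None and call.classification != "none":
            calls.append(call)
    return ContigScan(
        contig_id=pileup.contig_id,
        calls=calls,
        eligible_bases=int(eligible.sum()),
        assessable_bases={g: int(ok[gi].sum()) for gi, g in enumerate(GENOTYPES)},
        intra=intra,
    )


@dataclass
class SNPSummary:
    """Dataset-level variant tallies mirroring the four-way partition."""

    n_variant_positions: int
    n_case_a: int
    n_case_b: int
    n_case_c: int
    n_case_d: int
    eligible_bases: int
    intra_counts: dict[str, int] = field(default_factory=dict)
    intra_bases: dict[str, int] = field(default_factory=dict)
    ts_fraction: float = float("nan")
    biallelic_fraction: float = float("nan")

    @property
    def n_intergenotypic(self) -> int:
        return self.n_case_b + self.n_case_c + self.n_case_d

    @property
    def density_bp(self) -> float:
        """Consensus bp per inter-genotypic SNP (nan when none found)."""
        if self.n_intergenotypic == 0:
            return float("nan")
        return self.eligible_bases / self.n_intergenotypic

    def intra_density_bp(self, genotype: str) -> float:
        n = self.intra_counts.get(genotype, 0)
        return self.intra_bases.get(genotype, 0) / n if n else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("variant_positions", self.n_variant_positions),
            ("caseA_homoeo", self.n_case_a),
            ("caseB_Gh_poly", self.n_case_b),
            ("caseC_Gb_poly", self.n_case_c),
            ("caseD_fixed_diff", self.n_case_d),
            ("intergenotypic", self.n_intergenotypic),
            ("eligible_bases", self.eligible_bases),
            ("density_bp_per_intergenotypic_snp",
             round(self.density_bp) if self.n_intergenotypic else np.nan),
            ("ts_fraction", self.ts_fraction),
            ("biallelic_fraction", self.biallelic_fraction),
        ]
        for g in GENOTYPES:
            rows.append((f"intra_{g}_snps", self.intra_counts.get(g, 0)))
            rows.append((f"intra_{g}_bases", self.intra_bases.get(g, 0)))
        return pd.DataFrame(rows, columns=["quantity", "value"])


def snp_summary(
    scans: Iterable[ContigScan] | None = None,
    *,
    calls: Sequence[VariantCall] | None = None,
    eligible_bases: int | None = None,
    intra_counts: Mapping[str, int] | None = None,
    intra_bases: Mapping[str, int] | None = None,
) -> SNPSummary:
    """Tally a set of contig scans (or pre-extracted calls) into a summary."""
    if scans is not None:
        scans = list(scans)
        calls = [c for s in scans for c in s.calls]
        eligible_bases = sum(s.eligible_bases for s in scans)
        intra_counts = {g: sum(len(s.intra[g]) for s in scans) for g in GENOTYPES}
        intra_bases = {g: sum(s.assessable_bases[g] for s in scans) for g in GENOTYPES}
    assert calls is not None and eligible_bases is not None
    by_class = {c: 0 for c in CASES}
    for call in calls:
        by_class[call.classification] += 1
    n_bi = sum(1 for c in calls if c.biallelic)
    n_ts = sum(1 for c in calls if c.substitution == "transition")
    n = len(calls)
    return SNPSummary(
        n_variant_positions=n,
        n_case_a=by_class["caseA_homoeo"],
        n_case_b=by_class["caseB_Gh_poly"],
        n_case_c=by_class["caseC_Gb_poly"],
        n_case_d=by_class["caseD_fixed_diff"],
        eligible_bases=int(eligible_bases),
        intra_counts=dict(intra_counts or {}),
        intra_bases=dict(intra_bases or {}),
        ts_fraction=n_ts / n_bi if n_bi else float("nan"),
        biallelic_fraction=n_bi / n if n else float("nan"),
    )


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def export_snp_flanks(
    calls: Sequence[VariantCall],
    consensus: Mapping[str, str],
    flank: int = 60,
) -> pd.DataFrame:
    """Flanked-SNP records: ``LEFT[ref/alt]RIGHT`` with flanks truncated at
    contig ends; the record name joins contig id and unpadded position."""
    rows = []
    for call in calls:
        seq = consensus[call.contig_id]
        i = call.position - 1
        if not 0 <= i < len(seq):
            raise ValueError(
                f"{call.contig_id}: SNP position {call.position} outside consensus"
            )
        ref = seq[i]
        alts = [a for a in call.alleles if a != ref] or [a for a in call.alleles]
        left = seq[max(0, i - flank) : i]
        right = seq[i + 1 : i + 1 + flank]
        rows.append(
            {
                "name": f"{call.contig_id}_{call.position}",
                "contig": call.contig_id,
                "pos": call.position,
                "classification": call.classification,
                "sequence": f"{left}[{ref}/{'/'.join(alts)}]{right}",
            }
        )
    return pd.DataFrame(rows, columns=["name", "contig", "pos", "classification", "sequence"])


def export_vcf(
    calls: Sequence[VariantCall],
    consensus: Mapping[str, str],
    path: str | Path,
) -> None:
    """Write calls as VCF 4.2 with one sample column per genotype and the
    partition class in INFO."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=CLASS,Number=1,Type=String,Description="Variant partition class">',
        '##INFO=<ID=SUBST,Number=1,Type=String,Description="Substitution type">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for cid in sorted({c.contig_id for c in calls}):
        lines.append(f"##contig=<ID={cid},length={len(consensus[cid])}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(GENOTYPES))
    for call in sorted(calls, key=lambda c: (c.contig_id, c.position)):
        seq = consensus[call.contig_id]
        i = call.position - 1
        if not 0 <= i < len(seq):
            raise ValueError(
                f"{call.contig_id}: SNP position {call.position} outside consensus"
            )
        ref = seq[i]
        alts = sorted(set(call.alleles) - {ref})
        order = [ref] + alts
        gts = []
        for g in GENOTYPES:
            idx = sorted(order.index(a) for a in call.called[g]) or [0]
            if len(idx) == 1:
                idx = idx * 2
            gts.append("/".join(str(j) for j in idx[:2]))
        lines.append(
            "\t".join(
                [
                    call.contig_id,
                    str(call.position),
                    f"{call.contig_id}_{call.position}",
                    ref,
                    ",".join(alts) if alts else ".",
                    ".",
                    "PASS",
                    f"CLASS={call.classification};SUBST={call.substitution}",
                    "GT",
                    *gts,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def calls_frame(calls: Sequence[VariantCall]) -> pd.DataFrame:
    rows = [
        {
            "contig": c.contig_id,
            "pos": c.position,
            "classification": c.classification,
            "alleles": "/".join(c.alleles),
            "called_Gh": "/".join(c.called["Gh"]),
            "called_Gb": "/".join(c.called["Gb"]),
            "biallelic": c.biallelic,
            "substitution": c.substitution,
            "mono_matches_poly": c.mono_matches_poly,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=["contig", "pos", "classification", "alleles", "called_Gh",
                 "called_Gb", "biallelic", "substitution", "mono_matches_poly"],
    )
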