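"""Pipeline orchestration and summary tables.

Runs the full synthetic-data pipeline (simulate -> filter -> tag -> pileup ->
DGE -> SNP -> SSR -> primers -> report) from one declarative configuration,
and produces the dataset-level tables: sequencing statistics, assembly
statistics, the most abundant transcripts, and the differential-expression
roll-ups. Every total a table prints equals the sum of its printed parts;
report cells round means to one decimal, lengths to integer bp and
percentages to integers.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import dge, snp, ssr, tagging
from .aio import (
    GENOTYPES,
    LIBRARIES,
    STAGES,
    ContigAlignment,
    TaggedRead,
    build_pileup,
    genotype_of_library,
    stage_of_library,
    trim_filter_reads,
)
from .sim import SimConfig, simulate_reads, simulate_transcriptome, write_dataset
from .snp import CallParams
from .tagging import ProgenitorPanel

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One declarative configuration for the whole pipeline.

    Thresholds default to the analysis conventions: 100-bp read-length
    filter, depth >= 6 with a 10% / 2-read minor-allele rule for SNP calls,
    p < 0.05 with fold >= 2 for differential expression, and tagging with
    11-mer seeds at a minimum score of 30.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    outdir: str = "results/run"
    min_len: int = 100
    min_depth: int = 6
    maf: float = 0.10
    min_minor: int = 2
    alpha: float = 0.05
    min_fold: float = 2.0
    tag_min_score: int = 30
    tag_seed_k: int = 11
    ssr_min_repeats: dict[int, int] = field(
        default_factory=lambda: dict(ssr.DEFAULT_MIN_REPEATS)
    )
    ssr_max_interruption: int = 100
    ssr_min_flank: int = 50
    snp_flank: int = 60
    tag_reads: bool = True

    def validate(self) -> None:
        self.sim.validate()
        if self.min_len < 1 or self.min_depth < 1 or self.min_minor < 0:
            raise ValueError("thresholds out of range")
        if not 0 < self.alpha < 1 or not 0 <= self.maf <= 1 or self.min_fold < 1:
            raise ValueError("thresholds out of range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        if "gene_length_range" in sim_raw:
            sim_raw["gene_length_range"] = tuple(sim_raw["gene_length_range"])
        if "library_sizes" in sim_raw and sim_raw["library_sizes"] is not None:
            sim_raw["library_sizes"] = tuple(sim_raw["library_sizes"].items())
        if "ssr_min_repeats" in raw:
            raw["ssr_min_repeats"] = {int(k): int(v) for k, v in raw["ssr_min_repeats"].items()}
        cfg = cls(sim=SimConfig(**sim_raw), **raw)
        cfg.validate()
        return cfg


# ---------------------------------------------------------------------------
# Summary tables
# ---------------------------------------------------------------------------

def sequencing_summary(
    reads: Sequence[TaggedRead], min_len: int = 100
) -> pd.DataFrame:
    """Per-library and total sequencing statistics (reads, bases, mean
    length, short reads, high-quality reads)."""
    _, _, per_lib = trim_filter_reads(reads, min_len)
    for lib in LIBRARIES:
        if per_lib.loc[lib, "n_reads"] == 0:
            logger.warning("library %s is empty", lib)
    return _finish_table1(per_lib)


def sequencing_summary_from_counts(
    per_library: Mapping[str, Mapping[str, int]]
) -> pd.DataFrame:
    """Same table computed from per-library printed statistics
    (`n_reads`, `n_bases`, `n_short` per library)."""
    rows = []
    for lib in LIBRARIES:
        d = per_library[lib]
        n, bases, short = int(d["n_reads"]), int(d["n_bases"]), int(d["n_short"])
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
    return _finish_table1(pd.DataFrame(rows).set_index("library"))


def _finish_table1(per_lib: pd.DataFrame) -> pd.DataFrame:
    total = per_lib[["n_reads", "n_bases", "n_short", "n_high_quality"]].sum()
    out = per_lib.copy()
    out.loc["total"] = {
        "n_reads": int(total["n_reads"]),
        "n_bases": int(total["n_bases"]),
        "mean_length": round(total["n_bases"] / total["n_reads"], 1)
        if total["n_reads"]
        else 0.0,
        "n_short": int(total["n_short"]),
        "n_high_quality": int(total["n_high_quality"]),
    }
    out["mean_length_bp"] = out["mean_length"].round().astype(int)
    return out


def assembly_summary(alignments: Sequence[ContigAlignment]) -> dict[str, float]:
    """Unigene statistics from contig alignments (one-read contigs count as
    singletons, the assembler-level distinction being out of reach here)."""
    n_reads = [len(a.placements) for a in alignments]
    n_contigs = sum(1 for n in n_reads if n >= 2)
    n_singletons = sum(1 for n in n_reads if n == 1)
    reads_in_contigs = sum(n for n in n_reads if n >= 2)
    lengths = [a.unpadded_length for a in alignments if len(a.placements) >= 2]
    return _finish_assembly(n_contigs, n_singletons, reads_in_contigs, lengths)


def assembly_summary_from_counts(
    n_contigs: int, n_singletons: int, reads_in_contigs: int
) -> dict[str, float]:
    return _finish_assembly(n_contigs, n_singletons, reads_in_contigs, [])


def _finish_assembly(
    n_contigs: int, n_singletons: int, reads_in_contigs: int, lengths: Sequence[int]
) -> dict[str, float]:
    return {
        "n_contigs": n_contigs,
        "n_singletons": n_singletons,
        "n_unigenes": n_contigs + n_singletons,
        "reads_in_contigs": reads_in_contigs,
        "mean_reads_per_contig": round(reads_in_contigs / n_contigs, 1) if n_contigs else 0.0,
        "mean_contig_length_bp": round(float(np.mean(lengths))) if len(lengths) else 0,
    }


def top_transcripts(count_table: pd.DataFrame, n: int = 10) -> pd.DataFrame:
    """Rank contigs by total reads, with genotype and stage margins.

    The per-genotype and per-stage sums each add back up to the total
    (Gh + Gb = 10dpa + 22dpa = total); ties order stably by contig id.
    """
    out = pd.DataFrame(index=count_table.index)
    out["total"] = count_table[list(LIBRARIES)].sum(axis=1)
    for g in GENOTYPES:
        out[g] = count_table[[l for l in LIBRARIES if l.startswith(g)]].sum(axis=1)
    for s in STAGES:
        out[f"dpa{s}"] = count_table[[l for l in LIBRARIES if l.endswith(s)]].sum(axis=1)
    out = out.sort_index().sort_values("total", ascending=False, kind="stable")
    return out.head(n)


def differential_summary(matrix: pd.DataFrame) -> dict[str, int]:
    """Roll-ups over the factorial comparison matrix (stage, genotype, tag
    totals as up-side-1 plus up-side-2 of the overall comparisons)."""
    out: dict[str, int] = {}
    for name, key in (("10_vs_22", "stage"), ("Gh_vs_Gb", "genotype"), ("A_vs_D", "tag")):
        row = matrix[matrix["comparison"] == name]
        if row.empty:
            continue
        r = row.iloc[0]
        out[f"{key}_up_{r['side1']}"] = int(r["n_up1"])
        out[f"{key}_up_{r['side2']}"] = int(r["n_up2"])
        out[f"{key}_differential_total"] = int(r["n_up1"] + r["n_up2"])
    return out


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def count_tables(
    alignments: Sequence[ContigAlignment],
    read_library: Mapping[str, str],
    read_tag: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Contig x library counts (and contig x library_tag counts when tags
    are supplied) from placed reads."""
    idx = [a.contig_id for a in alignments]
    table = pd.DataFrame(0, index=idx, columns=list(LIBRARIES), dtype=np.int64)
    tag_cols = [f"{l}_{t}" for l in LIBRARIES for t in ("A", "D")]
    tag_table = pd.DataFrame(0, index=idx, columns=tag_cols, dtype=np.int64)
    for a in alignments:
        for p in a.placements:
            lib = read_library[p.read_id]
            table.loc[a.contig_id, lib] += 1
            if read_tag is not None:
                t = read_tag.get(p.read_id, "unknown")
                if t in ("A", "D"):
                    tag_table.loc[a.contig_id, f"{lib}_{t}"] += 1
    return table, (tag_table if read_tag is not None else None)


def run_pipeline(config: RunConfig) -> dict[str, object]:
    """Execute the full synthetic pipeline; every stage output is written
    under `config.outdir` and the in-memory results are returned.

    Deterministic: identical configuration (including the seed) reproduces
    identical output files byte for byte.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, object] = {}
    log_lines = [f"config: {json.dumps(_config_dict(config), sort_keys=True)}"]

    def stage(name: str):
        logger.info("pipeline stage: %s", name)
        log_lines.append(f"stage: {name}")

    try:
        stage("simulate")
        truth = simulate_transcriptome(config.sim)
        readset = simulate_reads(truth)
        write_dataset(truth, readset, out / "data")
        results["truth"], results["readset"] = truth, readset

        stage("trim_filter")
        all_reads = readset.all_reads()
        kept, _discarded, filter_summary = trim_filter_reads(all_reads, config.min_len)
        filter_summary.to_csv(out / "filter_summary.tsv", sep="\t")
        kept_ids = {r.id for r in kept}
        results["filter_summary"] = filter_summary
        log_lines.append(f"min_len: {config.min_len}")

        stage("tag")
        read_tag: dict[str, str] | None = None
        if config.tag_reads:
            panel_a, panel_d = truth.progenitor_panels()
            pa = ProgenitorPanel("A", panel_a)
            pd_ = ProgenitorPanel("D", panel_d)
            decisions, tag_summary = tagging.tag_library(
                kept, pa, pd_, config.tag_min_score, config.tag_seed_k
            )
            decisions.to_csv(out / "tag_decisions.tsv", sep="\t", index=False)
            tag_summary.to_csv(out / "tag_summary.tsv", sep="\t")
            read_tag = dict(zip(decisions["read_id"], decisions["tag"]))
            results["tag_summary"] = tag_summary
            log_lines.append(
                f"tag_min_score: {config.tag_min_score}; seed_k: {config.tag_seed_k}"
            )

        stage("count")
        alignments = [
            ContigAlignment(
                a.contig_id, a.consensus, [p for p in a.placements if p.read_id in kept_ids]
            )
            for a in readset.alignments
        ]
        read_library = {r.id: r.library for r in kept}
        table, tag_table = count_tables(alignments, read_library, read_tag)
        table.to_csv(out / "counts.tsv", sep="\t")
        if tag_table is not None:
            tag_table.to_csv(out / "counts_tagged.tsv", sep="\t")
        results["counts"], results["tag_counts"] = table, tag_table

        stage("dge")
        matrix = dge.comparison_matrix(
            table, tag_table, alpha=config.alpha, min_fold=config.min_fold
        )
        matrix.to_csv(out / "dge_comparisons.tsv", sep="\t", index=False)
        stage_res = dge.compare_groups(
            table,
            dge.ComparisonSpec("10_vs_22", ("Gh10", "Gb10"), ("Gh22", "Gb22"), "10", "22"),
            alpha=config.alpha,
            min_fold=config.min_fold,
        )
        stage_res.to_csv(out / "dge_stage.tsv", sep="\t")
        results["dge_matrix"], results["dge_stage"] = matrix, stage_res
        log_lines.append(f"alpha: {config.alpha}; min_fold: {config.min_fold}")

        stage("snp")
        params = CallParams(config.min_depth, config.maf, config.min_minor)
        scans = [
            snp.scan_contig(build_pileup(a, read_library, read_tag), params)
            for a in alignments
        ]
        calls = [c for s in scans for c in s.calls]
        summary = snp.snp_summary(scans)
        snp.calls_frame(calls).to_csv(out / "snp_calls.tsv", sep="\t", index=False)
        summary.to_frame().to_csv(out / "snp_summary.tsv", sep="\t", index=False)
        consensus = {a.contig_id: a.unpadded_consensus for a in alignments}
        snp.export_snp_flanks(calls, consensus, config.snp_flank).to_csv(
            out / "snp_flanks.tsv", sep="\t", index=False
        )
        snp.export_vcf(calls, consensus, out / "snps.vcf")
        results["snp_scans"], results["snp_summary"] = scans, summary
        log_lines.append(
            f"min_depth: {config.min_depth}; maf: {config.maf}; min_minor: {config.min_minor}"
        )

        stage("ssr")
        ssr_records = [
            r
            for a in alignments
            for r in ssr.find_ssrs(
                a.unpadded_consensus,
                config.ssr_min_repeats,
                config.ssr_max_interruption,
                contig_id=a.contig_id,
            )
        ]
        ssr.records_frame(ssr_records).to_csv(out / "ssr_records.tsv", sep="\t", index=False)
        type_table, class_freq = ssr.ssr_summary(ssr_records)
        type_table.to_csv(out / "ssr_summary.tsv", sep="\t", index=False)
        class_freq.to_csv(out / "ssr_classes.tsv", sep="\t", index=False)
        results["ssr_records"], results["ssr_summary"] = ssr_records, type_table
        log_lines.append(
            f"ssr_min_repeats: {config.ssr_min_repeats}; "
            f"max_interruption: {config.ssr_max_interruption}"
        )

        stage("primers")
        triplets = []
        for call in calls:
            if call.classification in ("caseB_Gh_poly", "caseC_Gb_poly", "caseD_fixed_diff") \
                    and call.biallelic:
                try:
                    triplets.append(
                        ssr.design_snp_triplet(call, consensus[call.contig_id])
                    )
                except ValueError:
                    continue
        ssr.triplets_frame(triplets).to_csv(out / "snp_primers.tsv", sep="\t", index=False)
        results["primer_triplets"] = triplets

        stage("report")
        table1 = sequencing_summary(all_reads, config.min_len)
        table1.to_csv(out / "table1_sequencing.tsv", sep="\t")
        asm = assembly_summary(alignments)
        pd.Series(asm).to_csv(out / "assembly_summary.tsv", sep="\t", header=False)
        top = top_transcripts(table)
        top.to_csv(out / "top_transcripts.tsv", sep="\t")
        diff = differential_summary(matrix)
        pd.Series(diff, dtype=np.int64).to_csv(
            out / "differential_summary.tsv", sep="\t", header=False
        )
        results.update(
            table1=table1, assembly=asm, top_transcripts=top, differential=diff
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {log_lines[-1]!r}: {exc}") from exc

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return results


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["ssr_min_repeats"] = {str(k): v for k, v in d["ssr_min_repeats"].items()}
    return d
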