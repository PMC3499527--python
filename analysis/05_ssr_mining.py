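"""Scan contig consensus sequences for microsatellites.

MISA-parameterised: at least 10 repeats for mononucleotides, 6 for
dinucleotides, 5 for tri- to hexanucleotides, with qualifying repeats
within 100 bp merged into compound records. Candidates with at least 50 bp
of clean flank on both sides are retained for primer design.

Writes ssr_records.tsv, ssr_summary.tsv, ssr_classes.tsv and
ssr_design_candidates.tsv under results/.
"""

from pathlib import Path

from polyest import ssr
from polyest.aio import read_fasta

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    records = []
    candidates = []
    for rec in read_fasta(DATA / "consensus.fasta"):
        found = ssr.find_ssrs(str(rec.seq), contig_id=rec.id)
        records += found
        candidates += ssr.filter_design_candidates(found, len(rec.seq), min_flank=50)
    ssr.records_frame(records).to_csv(OUT / "ssr_records.tsv", sep="\t", index=False)
    type_table, class_freq = ssr.ssr_summary(records)
    type_table.to_csv(OUT / "ssr_summary.tsv", sep="\t", index=False)
    class_freq.to_csv(OUT / "ssr_classes.tsv", sep="\t", index=False)
    ssr.records_frame(candidates).to_csv(
        OUT / "ssr_design_candidates.tsv", sep="\t", index=False
    )
    print(type_table.to_string(index=False))
    print(f"{len(candidates)} SSRs with >= 50 bp flanks kept as design candidates")
    if not class_freq.empty:
        print("motif classes:")
        print(class_freq.to_string(index=False))


if __name__ == "__main__":
    main()
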