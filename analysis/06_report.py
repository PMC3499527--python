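"""Assemble the dataset-level summary tables.

Produces the sequencing-statistics table (per-library reads, bases, mean
length, short and high-quality reads, with totals), the assembly/unigene
statistics, and the differential-expression roll-ups from the comparison
matrix. Every printed total is the sum of its printed parts.

Writes table1_sequencing.tsv, assembly_summary.tsv and
differential_summary.tsv under results/.
"""

from pathlib import Path

import pandas as pd

from polyest.aio import read_alignment_tsv, read_fasta
from polyest.report import assembly_summary, differential_summary, sequencing_summary

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    from polyest.aio import LIBRARIES, TaggedRead

    reads = []
    for lib in LIBRARIES:
        reads += [
            TaggedRead(r.id, str(r.seq), lib)
            for r in read_fasta(DATA / f"reads_{lib}.fasta")
        ]
    table1 = sequencing_summary(reads, min_len=100)
    table1.to_csv(OUT / "table1_sequencing.tsv", sep="\t")
    print("sequencing statistics:")
    print(table1.to_string())

    consensus = {r.id: str(r.seq) for r in read_fasta(DATA / "consensus.fasta")}
    alignments = read_alignment_tsv(DATA / "alignments.tsv", consensus)
    asm = assembly_summary(alignments)
    pd.Series(asm).to_csv(OUT / "assembly_summary.tsv", sep="\t", header=False)
    print("assembly statistics:")
    for k, v in asm.items():
        print(f"  {k}: {v}")

    matrix = pd.read_csv(OUT / "dge_comparisons.tsv", sep="\t")
    diff = differential_summary(matrix)
    pd.Series(diff).to_csv(OUT / "differential_summary.tsv", sep="\t", header=False)
    print("differential-expression roll-ups:")
    for k, v in diff.items():
        print(f"  {k}: {v}")


if __name__ == "__main__":
    main()
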