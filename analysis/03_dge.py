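"""Digital gene expression over the factorial of pairwise comparisons.

Counts reads per contig per library (and per sub-genome tag), then runs
every stage / genotype / tag contrast — overall and nested within the other
factors — flagging contigs with Fisher p < 0.05 and at least 2-fold
normalised change.

Writes counts.tsv, counts_tagged.tsv, dge_comparisons.tsv, dge_stage.tsv
and top_transcripts.tsv under results/.
"""

from pathlib import Path

import pandas as pd

from polyest import dge
from polyest.aio import read_alignment_tsv, read_fasta
from polyest.report import count_tables, top_transcripts

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    consensus = {r.id: str(r.seq) for r in read_fasta(DATA / "consensus.fasta")}
    alignments = read_alignment_tsv(DATA / "alignments.tsv", consensus)
    decisions = pd.read_csv(OUT / "tag_decisions.tsv", sep="\t")
    read_library = {r: r.split(":")[0] for r in decisions["read_id"]}
    read_tag = dict(zip(decisions["read_id"], decisions["tag"]))
    kept = set(read_library)
    for aln in alignments:
        aln.placements = [p for p in aln.placements if p.read_id in kept]

    table, tag_table = count_tables(alignments, read_library, read_tag)
    table.to_csv(OUT / "counts.tsv", sep="\t")
    tag_table.to_csv(OUT / "counts_tagged.tsv", sep="\t")

    matrix = dge.comparison_matrix(table, tag_table)
    matrix.to_csv(OUT / "dge_comparisons.tsv", sep="\t", index=False)
    print("differential contigs per comparison:")
    print(matrix[["comparison", "n_up1", "n_up2", "p_pair"]].to_string(index=False))

    stage = dge.compare_groups(
        table,
        dge.ComparisonSpec("10_vs_22", ("Gh10", "Gb10"), ("Gh22", "Gb22"), "10", "22"),
    )
    stage.to_csv(OUT / "dge_stage.tsv", sep="\t")
    up10 = int((stage.flag == "group1").sum())
    up22 = int((stage.flag == "group2").sum())
    print(f"stage-differential contigs: {up10} up at 10 dpa, {up22} up at 22 dpa")

    top = top_transcripts(table)
    top.to_csv(OUT / "top_transcripts.tsv", sep="\t")
    print("most abundant transcripts (margins Gh+Gb = 10+22 = total):")
    print(top.to_string())


if __name__ == "__main__":
    main()
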