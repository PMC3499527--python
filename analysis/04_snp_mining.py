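"""Mine variants from the contig pileups and partition them.

Positions covered at depth >= 6 in both genotypes are classified into the
four cases: homoeo-SNPs (both genotypes polymorphic), allelic SNPs (one
genotype polymorphic, Gh or Gb), and fixed inter-genotypic differences
(both monomorphic for different alleles). Inter-genotypic positions are
exported with 60-bp flanks and as VCF, and biallelic ones get
allele-specific primer triplets.

Writes snp_calls.tsv, snp_summary.tsv, snp_flanks.tsv, snps.vcf and
snp_primers.tsv under results/.
"""

from pathlib import Path

import pandas as pd

from polyest import snp, ssr
from polyest.aio import build_pileup, read_alignment_tsv, read_fasta

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

    scans = [
        snp.scan_contig(build_pileup(a, read_library, read_tag)) for a in alignments
    ]
    calls = [c for s in scans for c in s.calls]
    summary = snp.snp_summary(scans)
    snp.calls_frame(calls).to_csv(OUT / "snp_calls.tsv", sep="\t", index=False)
    summary.to_frame().to_csv(OUT / "snp_summary.tsv", sep="\t", index=False)
    print(summary.to_frame().to_string(index=False))
    print(f"inter-genotypic SNP density: one per "
          f"{summary.density_bp:.0f} bp of dual-coverage consensus")

    inter = [c for c in calls if c.classification != "caseA_homoeo"]
    snp.export_snp_flanks(inter, consensus, flank=60).to_csv(
        OUT / "snp_flanks.tsv", sep="\t", index=False
    )
    snp.export_vcf(calls, consensus, OUT / "snps.vcf")

    triplets = []
    for call in inter:
        if call.biallelic:
            try:
                triplets.append(ssr.design_snp_triplet(call, consensus[call.contig_id]))
            except ValueError:
                continue  # too close to a contig end
    ssr.triplets_frame(triplets).to_csv(OUT / "snp_primers.tsv", sep="\t", index=False)
    print(f"{len(inter)} inter-genotypic SNPs exported; "
          f"{len(triplets)} primer triplets designed")


if __name__ == "__main__":
    main()
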