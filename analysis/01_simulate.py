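"""Generate the synthetic tetraploid fiber transcriptome dataset.

Emulates the study design: four 454-like libraries (two genotypes Gh/Gb at
two fiber stages, 10 and 22 dpa), genes carrying homoeo-substitutions
between the A and D sub-genome copies (1 per 80 bp) and allelic
substitutions between genotypes (1 per 108 bp), a 5% silenced-copy
fraction, 10% stage-differential gene copies at 4-fold, and 20,000 reads
of mean length 353 bp per library.

Writes reads, progenitor panels, truth tables and per-gene alignments under
results/data/.
"""

from polyest.sim import SimConfig, simulate_reads, simulate_transcriptome, write_dataset

OUT = "results/data"


def main() -> None:
    cfg = SimConfig(seed=0)
    truth = simulate_transcriptome(cfg)
    readset = simulate_reads(truth)
    write_dataset(truth, readset, OUT)
    n_reads = len(readset.all_reads())
    classes = truth.truth_frame()["expected_class"].value_counts()
    print(f"simulated {cfg.n_genes} genes, {n_reads} reads -> {OUT}/")
    print("planted variant classes:")
    print(classes.to_string())


if __name__ == "__main__":
    main()
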