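"""Variant calling rules, the four-way partition, and exports."""

import numpy as np
import pytest

from polyest.aio import PositionCounts, build_pileup
from polyest.snp import (
    CASES,
    CallParams,
    SNPSummary,
    call_intra_genotype,
    calls_frame,
    classify_position,
    export_snp_flanks,
    export_vcf,
    scan_contig,
    snp_summary,
    ts_tv,
)


def pc(gh, gb, contig="c", pos=1):
    return PositionCounts(contig, pos, {"Gh": gh, "Gb": gb}, {})


class TestIntraCall:
    def test_balanced_site_is_polymorphic(self):
        assert call_intra_genotype({"A": 6, "G": 6}) == (True, True, ("A", "G"))

    def test_minor_below_ten_percent_is_monomorphic(self):
        # 2/21 = 9.5% fails the fraction rule despite 2 occurrences
        assert call_intra_genotype({"A": 19, "G": 2}) == (True, False, ("A",))

    def test_minor_needs_two_occurrences(self):
        assert call_intra_genotype({"A": 8, "G": 1}) == (True, False, ("A",))

    def test_below_depth_not_assessable(self):
        assert call_intra_genotype({"A": 5, "G": 5}, min_depth=11) == (False, False, ())
        assert call_intra_genotype({"A": 3, "G": 2}) == (False, False, ())

    def test_majority_tie_breaks_lexicographically(self):
        # forced with a permissive maf so neither allele qualifies as minor
        assessable, poly, alleles = call_intra_genotype(
            {"T": 5, "C": 5}, min_depth=6, maf=0.6, min_minor=2
        )
        assert (assessable, poly, alleles) == (True, False, ("C",))


class TestClassify:
    def test_both_polymorphic_is_homoeo(self):
        call = classify_position(pc({"A": 6, "G": 6}, {"A": 6, "G": 6}))
        assert call.classification == "caseA_homoeo"
        assert call.biallelic and call.substitution == "transition"

    def test_one_genotype_polymorphic_is_allelic(self):
        call = classify_position(pc({"A": 6, "G": 6}, {"A": 12}))
        assert call.classification == "caseB_Gh_poly"
        assert call.mono_matches_poly is True
        call = classify_position(pc({"A": 12}, {"A": 6, "G": 6}))
        assert call.classification == "caseC_Gb_poly"

    def test_fixed_difference_is_case_d(self):
        call = classify_position(pc({"A": 10}, {"G": 10}))
        assert call.classification == "caseD_fixed_diff"

    def test_same_monomorphic_allele_is_none(self):
        assert classify_position(pc({"A": 10}, {"A": 10})).classification == "none"

    def test_insufficient_dual_coverage_excluded(self):
        assert classify_position(pc({"A": 10}, {"G": 5})) is None


class TestTsTv:
    @pytest.mark.parametrize(
        "alleles,expect",
        [(("A", "G"), "transition"), (("T", "C"), "transition"),
         (("A", "C"), "transversion"), (("G", "T"), "transversion"),
         (("A", "C", "G"), "multi")],
    )
    def test_classes(self, alleles, expect):
        assert ts_tv(alleles) == expect

    def test_single_allele_rejected(self):
        with pytest.raises(ValueError):
            ts_tv(("A",))


class TestScan:
    def build(self, clean_sim, gene_pred=None):
        _, truth, readset = clean_sim
        gene = next(g for g in truth.genes if gene_pred is None or gene_pred(g))
        aln = next(a for a in readset.alignments if a.contig_id == gene.gene_id)
        return gene, build_pileup(aln, readset.read_library_map())

    def test_classes_match_truth_at_depth(self, clean_sim):
        """Error-free data: wherever both genotypes are well covered, the
        scan recovers exactly the planted classes."""
        _, truth, readset = clean_sim
        libmap = readset.read_library_map()
        n_checked = 0
        for aln in readset.alignments[:8]:
            gene = truth.gene(aln.contig_id)
            pile = build_pileup(aln, libmap)
            scan = scan_contig(pile)
            deep = (pile.by_genotype.sum(axis=2) >= 12).all(axis=0)
            predicted = {c.position: c.classification for c in scan.calls}
            for pos1, expect in (
                [(p + 1, gene.expected_class(p)) for p in gene.homoeo_positions]
                + [(p + 1, gene.expected_class(p)) for p, _, _ in gene.allelic_positions]
            ):
                if not deep[pos1 - 1]:
                    continue
                got = predicted.get(pos1, "none")
                assert got == expect, (aln.contig_id, pos1)
                n_checked += 1
            for pos1 in predicted:  # no false positives on error-free data
                assert (aln.contig_id, pos1) in truth.variant_classes()
        assert n_checked > 100

    def test_single_genotype_coverage_still_scans_intra(self):
        from polyest.aio import ContigAlignment, Placement

        reads = [Placement(f"r{i}", 0, "+", "ACGT") for i in range(6)] + [
            Placement(f"s{i}", 0, "+", "AGGT") for i in range(6)
        ]
        aln = ContigAlignment("c", "ACGT", reads)
        libmap = {p.read_id: "Gh10" for p in reads}
        scan = scan_contig(build_pileup(aln, libmap))
        assert scan.eligible_bases == 0 and not scan.calls
        assert scan.assessable_bases == {"Gh": 4, "Gb": 0}
        assert scan.intra["Gh"] == [(2, ("C", "G"))]

    def test_identical_reads_yield_no_variants(self):
        from polyest.aio import ContigAlignment, Placement

        aln = ContigAlignment(
            "c", "ACGTACGTACGT",
            [Placement(f"r{i}", 0, "+", "ACGTACGTACGT") for i in range(20)],
        )
        libmap = {f"r{i}": ["Gh10", "Gb22"][i % 2] for i in range(20)}
        scan = scan_contig(build_pileup(aln, libmap))
        assert not scan.calls and scan.eligible_bases == 12

    def test_raising_min_depth_never_adds_calls(self, clean_sim):
        _, truth, readset = clean_sim
        libmap = readset.read_library_map()
        for aln in readset.alignments[:5]:
            pile = build_pileup(aln, libmap)
            lo = scan_contig(pile, CallParams(min_depth=6))
            hi = scan_contig(pile, CallParams(min_depth=12))
            assert len(hi.calls) <= len(lo.calls)
            assert hi.eligible_bases <= lo.eligible_bases
            assert {c.position for c in hi.calls} <= {c.position for c in lo.calls}

    def test_partition_is_exhaustive_and_disjoint(self, clean_sim):
        _, truth, readset = clean_sim
        libmap = readset.read_library_map()
        scans = [scan_contig(build_pileup(a, libmap)) for a in readset.alignments[:6]]
        for s in scans:
            for c in s.calls:
                assert c.classification in CASES
        summ = snp_summary(scans)
        assert summ.n_variant_positions == sum(len(s.calls) for s in scans)
        assert summ.n_variant_positions == (
            summ.n_case_a + summ.n_case_b + summ.n_case_c + summ.n_case_d
        )
        assert summ.n_intergenotypic == summ.n_case_b + summ.n_case_c + summ.n_case_d


class TestSummaryArithmetic:
    def test_partition_totals_and_density(self):
        """The four-way tallies: 18,153 homoeo + 19,439 one-genotype + 1,507
        fixed = 39,099 variant positions; 20,946 inter-genotypic over
        2,257,950 eligible bp is one SNP per 108 bp."""
        s = SNPSummary(
            n_variant_positions=39_099, n_case_a=18_153, n_case_b=19_439,
            n_case_c=0, n_case_d=1_507, eligible_bases=2_257_950,
        )
        assert s.n_case_a + s.n_case_b + s.n_case_c + s.n_case_d == 39_099
        assert s.n_intergenotypic == 20_946
        assert round(s.density_bp) == 108

    def test_intra_density(self):
        s = SNPSummary(1, 0, 1, 0, 0, 100,
                       intra_counts={"Gh": 49_279}, intra_bases={"Gh": 4_040_878})
        assert round(s.intra_density_bp("Gh")) == 82

    def test_no_variants(self):
        s = snp_summary(calls=[], eligible_bases=0)
        assert s.n_variant_positions == 0
        assert np.isnan(s.density_bp)


class TestExports:
    def make_calls(self):
        consensus = {"ctg": "".join("ACGT"[i % 4] for i in range(200))}
        calls = []
        for pos in (61, 10, 195):
            ref = consensus["ctg"][pos - 1]
            alt = "A" if ref != "A" else "G"
            calls.append(
                classify_position(
                    pc({ref: 10}, {alt: 10}, contig="ctg", pos=pos)
                )
            )
        return consensus, calls

    def test_flank_lengths_and_truncation(self):
        consensus, calls = self.make_calls()
        df = export_snp_flanks(calls, consensus, flank=60).set_index("pos")
        full = df.loc[61, "sequence"]
        left, rest = full.split("[")
        _, right = rest.split("]")
        assert len(left) == 60 and len(right) == 60
        assert df.loc[61, "name"] == "ctg_61"
        left10 = df.loc[10, "sequence"].split("[")[0]
        assert len(left10) == 9
        right195 = df.loc[195, "sequence"].split("]")[1]
        assert len(right195) == 5

    def test_flank_bracket_shows_ref_and_alt(self):
        consensus, calls = self.make_calls()
        df = export_snp_flanks(calls, consensus).set_index("pos")
        ref = consensus["ctg"][60]
        assert f"[{ref}/" in df.loc[61, "sequence"]

    def test_position_outside_consensus_raises(self):
        consensus, calls = self.make_calls()
        calls[0].position = 999
        with pytest.raises(ValueError):
            export_snp_flanks(calls, consensus)

    def test_vcf_round_trip_remaps_alleles(self, tmp_path):
        consensus, calls = self.make_calls()
        path = tmp_path / "out.vcf"
        export_vcf(calls, consensus, path)
        body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert len(body) == len(calls)
        for line in body:
            chrom, pos, vid, ref, alt, _, _, info, fmt, gh, gb = line.split("\t")
            assert consensus[chrom][int(pos) - 1] == ref
            assert vid == f"{chrom}_{pos}"
            assert "CLASS=caseD_fixed_diff" in info
            order = [ref] + alt.split(",")
            call = next(c for c in calls if c.position == int(pos))
            assert order[int(gh[0])] in call.called["Gh"]
            assert order[int(gb[0])] in call.called["Gb"]

    def test_calls_frame_columns(self):
        consensus, calls = self.make_calls()
        df = calls_frame(calls)
        assert list(df["classification"].unique()) == ["caseD_fixed_diff"]
        assert set(df.columns) >= {"contig", "pos", "alleles", "substitution"}
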