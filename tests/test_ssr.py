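"""SSR mining (MISA conventions) and allele-specific primer triplets."""

import numpy as np
import pytest
from conftest import ssr_oracle
from hypothesis import given, settings
from hypothesis import strategies as st

from polyest.snp import classify_position
from polyest.aio import PositionCounts
from polyest.ssr import (
    DEFAULT_MIN_REPEATS,
    SSRRecord,
    canonical_motif,
    design_snp_triplet,
    filter_design_candidates,
    find_ssrs,
    motif_class,
    records_frame,
    ssr_summary,
)


def flanks(rng, n=120):
    """Random flanking sequence guaranteed SSR-free by rejection."""
    while True:
        s = "".join(rng.choice(list("ACGT"), n))
        if not find_ssrs(s):
            return s


class TestCanonicalMotif:
    def test_known_classes(self):
        assert canonical_motif("TC") == "AG"
        assert motif_class("TC") == "AG/CT"
        assert motif_class("AT") == "AT"  # reverse complement is a rotation

    def test_enumerated_example(self):
        # TAT: rotations {TAT, ATT, TTA} plus revcomp rotations {ATA, TAA, AAT}
        assert canonical_motif("TAT") == "AAT"

    def test_rejects_n_and_bad_length(self):
        with pytest.raises(ValueError):
            canonical_motif("AN")
        with pytest.raises(ValueError):
            canonical_motif("ACGTACG")

    @given(st.text(alphabet="ACGT", min_size=1, max_size=6))
    @settings(max_examples=200, derandomize=True)
    def test_idempotent_and_orbit_bounded(self, motif):
        canon = canonical_motif(motif)
        assert canonical_motif(canon) == canon
        rc = canon.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        orbit = {canon[i:] + canon[:i] for i in range(len(canon))} | {
            rc[i:] + rc[:i] for i in range(len(rc))
        }
        assert len(orbit) <= 2 * len(motif)
        assert all(canonical_motif(m) == canon for m in orbit)


class TestFindSsrs:
    def embed(self, rng, core):
        """Core between SSR-free flanks, with breaker bases so the planted
        run cannot extend across the boundary; returns (seq, core offset)."""
        left, right = flanks(rng), flanks(rng)
        return left + "CC" + core + "GG" + right, len(left) + 2

    def test_dinucleotide_threshold(self, rng):
        seq, off = self.embed(rng, "AT" * 6)
        (rec,) = find_ssrs(seq)
        assert (rec.motif, rec.unit_length, rec.repeat_count) == ("AT", 2, 6)
        assert rec.start == off + 1 and rec.end == off + 12
        assert not find_ssrs(self.embed(rng, "AT" * 5)[0])

    def test_mononucleotide_threshold_and_separation(self, rng):
        (rec,) = find_ssrs(self.embed(rng, "A" * 10)[0])
        assert rec.ssr_type == "p1" and rec.repeat_count == 10
        assert not find_ssrs(self.embed(rng, "A" * 9)[0])

    def test_degenerate_unit_reported_at_shortest_period(self):
        recs = find_ssrs("AT" * 6, min_repeats={2: 6, 4: 2, 6: 2})
        assert [(r.unit_length, r.motif, r.repeat_count) for r in recs] == [(2, "AT", 6)]

    def test_compound_merging_within_interruption(self, rng):
        gap = "CC" + flanks(rng)[:40] + "GG"  # breakers keep the runs maximal
        seq, _ = self.embed(rng, "AAG" * 5 + gap + "CT" * 7)
        (rec,) = find_ssrs(seq)
        assert rec.compound
        assert [m.motif for m in rec.members] == ["AAG", "CT"]
        starts = [m.start for m in rec.members]
        ends = [m.end for m in rec.members]
        assert starts == sorted(starts) and ends[0] < starts[1]  # ordered, disjoint
        far, _ = self.embed(rng, "AAG" * 5 + "CC" + flanks(rng)[:101] + "GG" + "CT" * 7)
        assert all(not r.compound for r in find_ssrs(far))

    def test_interval_arithmetic_invariant(self, rng):
        for _ in range(5):
            seq = "".join(rng.choice(list("ACGT"), 3000))
            for rec in find_ssrs(seq):
                if not rec.compound:
                    assert rec.length == rec.unit_length * rec.repeat_count
                    unit = seq[rec.start - 1 : rec.start - 1 + rec.unit_length]
                    assert seq[rec.start - 1 : rec.end] == unit * rec.repeat_count

    def test_matches_regex_oracle(self, rng):
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), 10_000))
            got = [
                (r.start, r.end, "compound" if r.compound else r.motif,
                 [(m.start, m.end, m.motif) for m in r.members])
                for r in sorted(find_ssrs(seq), key=lambda r: r.start)
            ]
            assert sorted(got) == ssr_oracle(seq, DEFAULT_MIN_REPEATS, 100)


class TestSummary:
    def test_type_totals(self):
        records = []
        for p, n in [(2, 1016), (3, 1570), (4, 81), (5, 21), (6, 112)]:
            records += [
                SSRRecord(1, p * 5, "ACGTAC"[:p], p, 5) for _ in range(n)
            ]
        records += [
            SSRRecord(1, 30, "compound", 0, 0, compound=True) for _ in range(333)
        ]
        table, _ = ssr_summary(records)
        table = table.set_index("ssr_type")["count"]
        assert table["total_p2_to_compound"] == 3133
        assert table["p2"] == 1016 and table["compound"] == 333

    def test_mononucleotides_excluded_from_total(self):
        records = [SSRRecord(1, 10, "A", 1, 10), SSRRecord(1, 12, "AT", 2, 6)]
        table, freq = ssr_summary(records)
        t = table.set_index("ssr_type")["count"]
        assert t["p1"] == 1 and t["total_p2_to_compound"] == 1
        assert set(freq["ssr_class"]) == {"A/T", "AT"}

    def test_empty(self):
        table, freq = ssr_summary([])
        assert (table["count"] == 0).all() and freq.empty


class TestDesignFilter:
    def test_flank_rules(self):
        recs = [SSRRecord(10, 21, "AT", 2, 6), SSRRecord(500, 511, "AT", 2, 6)]
        kept = filter_design_candidates(recs, seq_length=1000, min_flank=50)
        assert kept == [recs[1]]

    def test_all_ssr_contig_removed(self):
        rec = SSRRecord(1, 60, "AT", 2, 30)
        assert filter_design_candidates([rec], seq_length=60) == []

    def test_min_flank_validated(self):
        with pytest.raises(ValueError):
            filter_design_candidates([], 100, min_flank=0)


class TestPrimerTriplet:
    def make_call(self, consensus, pos, a1, a2):
        return classify_position(
            PositionCounts("ctg", pos, {"Gh": {a1: 10}, "Gb": {a2: 10}}, {})
        )

    def consensus(self, rng, n=500):
        return "".join(rng.choice(list("ACGT"), n))

    def test_lengths_alleles_and_size_difference(self, rng):
        seq = self.consensus(rng)
        call = self.make_call(seq, 200, "A", "G")
        t = design_snp_triplet(call, seq)
        assert len(t.forward1) == 35 and len(t.forward2) == 25
        assert t.forward1.endswith("A") and t.forward2.endswith("G")
        assert t.size_difference == 10

    def test_mismatch_at_minus_four_differs_from_template(self, rng):
        seq = self.consensus(rng)
        call = self.make_call(seq, 300, "A", "C")
        t = design_snp_triplet(call, seq)
        for primer, mb in ((t.forward1, t.mismatch_base1), (t.forward2, t.mismatch_base2)):
            assert primer[-4] == mb != t.template_base
        assert t.mismatch_base1 != t.mismatch_base2

    def test_annealing_region_matches_template_outside_mismatch(self, rng):
        seq = self.consensus(rng)
        call = self.make_call(seq, 250, "A", "G")
        t = design_snp_triplet(call, seq)
        core = t.forward1[-20:]
        template = seq[250 - 20 : 250]
        diffs = [i for i in range(20) if core[i] != template[i]]
        # only the -4 mismatch and possibly the allele terminus differ
        assert set(diffs) <= {16, 19}
        from polyest._dna import revcomp

        assert revcomp(t.reverse) in seq

    def test_insufficient_flank_errors_name_the_side(self, rng):
        seq = self.consensus(rng)
        with pytest.raises(ValueError, match="upstream"):
            design_snp_triplet(self.make_call(seq, 10, "A", "G"), seq)
        with pytest.raises(ValueError, match="downstream"):
            design_snp_triplet(self.make_call(seq, 495, "A", "G"), seq)

    def test_multiallelic_rejected(self, rng):
        seq = self.consensus(rng)
        call = classify_position(
            PositionCounts("ctg", 200, {"Gh": {"A": 6, "G": 6}, "Gb": {"T": 12}}, {})
        )
        with pytest.raises(ValueError):
            design_snp_triplet(call, seq)


def test_records_frame_shape(rng):
    seq = flanks(rng) + "AT" * 8 + flanks(rng)
    df = records_frame(find_ssrs(seq, contig_id="ctg1"))
    assert list(df["contig"]) == ["ctg1"]
    assert df.loc[0, "ssr_class"] == "AT"
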