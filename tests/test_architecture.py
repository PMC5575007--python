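"""Structure context, poly(U) distance, mRNA windows, bipartite spacing
and conservation profiling."""

import pytest

from arnscan.architecture import (
    bipartite_regions,
    conservation_profile,
    find_hairpins,
    folding_constraints,
    motif_context,
    mrna_window,
    native_spacing,
    poly_u_distance,
)
from arnscan.seqio import (
    Alignment,
    DotBracketStructure,
    Interval,
    RnaSequence,
    from_native,
    to_native,
)

from .oracles import nussinov, pairing_table


def db(brackets, sid="s"):
    return DotBracketStructure(seq_id=sid, brackets=brackets)


class TestHairpins:
    def test_single_hairpin(self):
        (h,) = find_hairpins(db("((((....))))"))
        assert (h.loop.start, h.loop.end) == (5, 8)
        assert (h.stem5.start, h.stem5.end) == (1, 4)
        assert (h.stem3.start, h.stem3.end) == (9, 12)

    def test_unstructured(self):
        assert find_hairpins(db("." * 12)) == []

    def test_two_hairpins(self):
        hps = find_hairpins(db("((..))..((...))"))
        assert len(hps) == 2
        assert hps[0].loop == Interval("s", 3, 4)
        assert hps[1].loop == Interval("s", 11, 13)

    def test_unbalanced_rejected(self):
        with pytest.raises(ValueError):
            db("((..)")

    def test_consistent_with_pairing_table_oracle(self):
        for brackets in (
            "((((....))))",
            "((..))..((...))",
            "(((..(((...)))..)))",
            "..((((((....))).)))..",
        ):
            pairs = pairing_table(brackets)
            for h in find_hairpins(db(brackets)):
                # stems pairwise disjoint from loop; stacked pairing
                assert h.stem5.end < h.loop.start <= h.loop.end < h.stem3.start
                for k in range(h.stem5.length):
                    assert pairs[h.stem5.end - k] == h.stem3.start + k

    def test_on_fabricated_fold(self, rng):
        # a fold produced by a maximum-pairing folder still parses into
        # hairpins consistent with its own pair table
        seq = "GGGGAAAACCCCAAAGGGGUUUUCCCC"
        brackets = nussinov(seq)
        pairs = pairing_table(brackets)
        for h in find_hairpins(db(brackets)):
            assert pairs[h.stem5.end] == h.stem3.start


class TestMotifContext:
    def test_embraced_between_two_hairpins(self):
        st = db("((((...))))" + "." * 12 + "((((...))))")
        ctx = motif_context(Interval("s", 13, 21), st)
        assert ctx.embraced
        assert ctx.mostly_unpaired

    def test_only_3prime_flank_at_sequence_start(self):
        st = db("." * 12 + "((((...))))")
        ctx = motif_context(Interval("s", 1, 10), st)
        assert ctx.hairpin_5p is None
        assert ctx.hairpin_3p is not None
        assert not ctx.embraced

    def test_fully_paired_motif_not_unpaired(self):
        st = db("((((((....))))))")
        ctx = motif_context(Interval("s", 1, 6), st)
        assert not ctx.mostly_unpaired

    def test_offset_handling(self):
        st = db("((((...))))" + "." * 12 + "((((...))))")
        # same structure, sequence numbered from 57
        ctx = motif_context(Interval("s", 69, 77), st, offset=57)
        assert ctx.embraced


class TestPolyU:
    def test_constructed_distance(self):
        res = "A" * 50 + "C" * 30 + "UUUUUU"
        seq = RnaSequence(id="s", residues=res)
        d = poly_u_distance(seq, Interval("s", 40, 50))
        assert d == 30

    def test_no_u_run(self):
        seq = RnaSequence(id="s", residues="A" * 30 + "CGCGCG")
        assert poly_u_distance(seq, Interval("s", 1, 12)) is None

    def test_run_outside_window_ignored(self):
        res = "UUUUUU" + "A" * 30 + "C" * 20
        seq = RnaSequence(id="s", residues=res)
        assert poly_u_distance(seq, Interval("s", 10, 20)) is None

    def test_short_run_not_a_tail(self):
        seq = RnaSequence(id="s", residues="A" * 20 + "UUU")
        assert poly_u_distance(seq, Interval("s", 1, 12), min_u_run=4) is None


class TestMrnaWindow:
    def _mrna(self, utr_len=120, cds_len=120):
        res = "C" * utr_len + "AUG" + "G" * (cds_len - 3)
        return RnaSequence(id="gene", residues=res), utr_len + 1

    def test_annotated_utr(self):
        seq, cds = self._mrna()
        win, wseq = mrna_window(seq, cds_start=cds, utr_start=-120)
        assert (win.window.start, win.window.end) == (-120, 80)
        assert len(wseq) == 200  # 120 upstream + 80 coding, no position 0

    def test_unannotated_defaults_to_minus_80(self):
        seq, cds = self._mrna()
        win, wseq = mrna_window(seq, cds_start=cds)
        assert (win.window.start, win.window.end) == (-80, 80)
        assert wseq.residues[80:83] == "AUG"

    def test_start_codon_at_sequence_start(self, caplog):
        seq = RnaSequence(id="g", residues="AUG" + "G" * 100)
        with caplog.at_level("WARNING"):
            win, wseq = mrna_window(seq, cds_start=1)
        assert (win.window.start, win.window.end) == (1, 80)
        assert "clipped" in caplog.text

    def test_roundtrip_no_position_zero(self):
        seq, cds = self._mrna()
        _, wseq = mrna_window(seq, cds_start=cds)
        natives = [to_native(wseq, i) for i in range(1, len(wseq) + 1)]
        assert 0 not in natives
        assert natives[79] == -1 and natives[80] == 1
        for i, n in enumerate(natives, start=1):
            assert from_native(wseq, n) == i


class TestBipartite:
    def test_spacing_across_missing_zero(self):
        # hand check: strictly between -55 and -10 lie -54..-11 = 44 nt
        pairs = bipartite_regions(
            [Interval("m", -70, -55), Interval("m", -10, 5)]
        )
        (rec,) = pairs
        assert rec["spacing_nt"] == 44
        assert rec["candidate_bipartite"]

    def test_single_region_no_pairs(self):
        assert bipartite_regions([Interval("m", -10, 5)]) == []

    def test_three_regions_two_consecutive_pairs(self):
        recs = bipartite_regions(
            [Interval("m", -120, -100), Interval("m", -50, -40), Interval("m", 10, 20)]
        )
        assert len(recs) == 2

    def test_native_spacing_positive_coords(self):
        assert native_spacing(10, 41) == 30


class TestConservation:
    def _aln(self, rows):
        return Alignment(rows=tuple(rows))

    def test_identical_rows_fully_persistent(self):
        aln = self._aln([("ref", "AAAAAGAAA"), ("h1", "AAAAAGAAA")])
        prof = conservation_profile(aln, "ref", Interval("ref", 1, 9))
        assert prof["persistence"] == 1.0
        assert all(c["conservation"] == 1.0 for c in prof["columns"])

    def test_one_mutant_row_in_ten(self):
        rows = [("ref", "AAAAAAAAA")] + [
            (f"h{i}", "AAAAAAAAA") for i in range(8)
        ]
        rows.append(("h9", "CAAAAAAAA"))  # A->C at the first A-site
        prof = conservation_profile(
            self._aln(rows), "ref", Interval("ref", 1, 9)
        )
        first_a = next(c for c in prof["columns"] if c["ref_position"] == 1)
        assert first_a["conservation"] == pytest.approx(0.9)
        assert prof["persistence"] == pytest.approx(0.9)

    def test_gap_column_flagged_persistence_on_remaining_rows(self):
        aln = self._aln(
            [
                ("ref", "AAAAAAAAA"),
                ("h1", "A-AAAAAAA"),  # gap at an R-site column
                ("h2", "AAAAAAAAA"),
            ]
        )
        prof = conservation_profile(aln, "ref", Interval("ref", 1, 9))
        assert any(c["flagged_gap"] for c in prof["columns"])
        assert prof["n_rows_evaluated"] == 2
        assert prof["persistence"] == 1.0

    def test_r_site_accepts_g(self):
        aln = self._aln([("ref", "AAU"), ("h1", "AGU")])
        prof = conservation_profile(aln, "ref", Interval("ref", 1, 3))
        r_col = next(c for c in prof["columns"] if c["site"] == "R")
        assert r_col["conservation"] == 1.0


class TestConstraints:
    def test_single_region(self):
        assert folding_constraints(Interval("s", 3, 5), 8) == "..xxx..."

    def test_whole_sequence(self):
        assert folding_constraints(Interval("s", 1, 6), 6) == "xxxxxx"

    def test_two_regions(self):
        out = folding_constraints([Interval("s", 1, 2), Interval("s", 5, 6)], 7)
        assert out == "xx..xx."

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            folding_constraints(Interval("s", 5, 12), 8)
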