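"""Seed complementarity search: 7-bp and 6+bulge+2 duplexes."""

import pytest

from arnscan.seed_finder import (
    GapStrand,
    SeedKind,
    SeedParams,
    find_seeds,
    map_seeds_to_regions,
)
from arnscan.seqio import DotBracketStructure, Interval, RnaSequence

from .conftest import random_rna
from .oracles import (
    brute_force_bulged_duplexes,
    brute_force_perfect_duplexes,
    _revcomp,
)


def rna(i, res, offset=1):
    return RnaSequence(id=i, residues=res, offset=offset)


class TestSevenBp:
    def test_g7_c7(self):
        seeds = find_seeds(rna("s", "GGGGGGG"), rna("m", "AUCCCCCCCUA"))
        (seed,) = seeds
        assert seed.kind is SeedKind.SEVEN_BP
        assert (seed.srna_interval.start, seed.srna_interval.end) == (1, 7)
        assert (seed.mrna_interval.start, seed.mrna_interval.end) == (3, 9)

    def test_a7_u7(self):
        (seed,) = find_seeds(rna("s", "AAAAAAA"), rna("m", "UUUUUUU"))
        assert seed.kind is SeedKind.SEVEN_BP
        assert seed.srna_interval.length == seed.mrna_interval.length == 7

    def test_maximal_duplexes_collapse_sliding_redundancy(self):
        # G9 vs C9: one maximal duplex per anti-diagonal of length >= 7
        # (9, 8, 8, 7, 7) instead of nine sliding 7-mers per diagonal
        seeds = find_seeds(rna("s", "GGGGGGGGG"), rna("m", "CCCCCCCCC"))
        sevens = [s for s in seeds if s.kind is SeedKind.SEVEN_BP]
        assert sorted(s.srna_interval.length for s in sevens) == [7, 7, 8, 8, 9]

    def test_all_minimal_flag_restores_sliding_hits(self):
        seeds = find_seeds(
            rna("s", "GGGGGGGGG"),
            rna("m", "CCCCCCCCC"),
            SeedParams(report_maximal=False),
        )
        sevens = [s for s in seeds if s.kind is SeedKind.SEVEN_BP]
        assert len(sevens) == 9  # 3 offsets x 3 anti-diagonal placements

    def test_abasic_never_pairs(self):
        assert find_seeds(rna("s", "GGG0GGG"), rna("m", "CCCCCCC")) == []

    def test_wobble_behind_flag(self):
        s, m = rna("s", "GGGGGGG"), rna("m", "UUUUUUU")
        assert find_seeds(s, m) == []
        assert any(
            sd.kind is SeedKind.SEVEN_BP
            for sd in find_seeds(s, m, SeedParams(allow_wobble=True))
        )


class TestBulged:
    def test_bulge_on_mrna(self):
        # sRNA GGGGGG+GG pairs mRNA CC+A+CCCCCC with the A bulged out
        seeds = find_seeds(rna("s", "GGGGGGGG"), rna("m", "CCACCCCCC"))
        (seed,) = [s for s in seeds if s.kind is SeedKind.SIX_GAP_TWO]
        assert seed.gap_strand is GapStrand.MRNA
        assert seed.srna_interval.length == 8
        assert seed.mrna_interval.length == 9

    def test_bulge_on_srna(self):
        seeds = find_seeds(rna("s", "GGGGGGAGG"), rna("m", "CCCCCCCC"))
        kinds = [s for s in seeds if s.kind is SeedKind.SIX_GAP_TWO]
        assert any(s.gap_strand is GapStrand.SRNA for s in kinds)

    def test_no_seed_shorter_than_seven_pairs(self):
        # 6 pairs alone, or 6+bulge+1, never qualify
        assert find_seeds(rna("s", "GGGGGG"), rna("m", "CCCCCC")) == []
        assert find_seeds(rna("s", "GGGGGGA"), rna("m", "CCCCCCC")) == []


class TestProperties:
    def test_symmetry_roles_swap(self, rng):
        for _ in range(30):
            a = rna("a", random_rna(rng, 20))
            b = rna("b", random_rna(rng, 20))
            fwd = find_seeds(a, b)
            rev = find_seeds(b, a)
            fwd_pairs = {
                (s.srna_interval.start, s.srna_interval.end,
                 s.mrna_interval.start, s.mrna_interval.end, s.kind)
                for s in fwd
            }
            rev_pairs = {
                (s.mrna_interval.start, s.mrna_interval.end,
                 s.srna_interval.start, s.srna_interval.end, s.kind)
                for s in rev
            }
            assert fwd_pairs == rev_pairs

    def test_reverse_complement_soundness(self, rng):
        for _ in range(30):
            a = rna("a", random_rna(rng, 25))
            b = rna("b", random_rna(rng, 25))
            for seed in find_seeds(a, b):
                if seed.kind is not SeedKind.SEVEN_BP:
                    continue
                s_seg = a.residues[
                    seed.srna_interval.start - 1 : seed.srna_interval.end
                ]
                m_seg = b.residues[
                    seed.mrna_interval.start - 1 : seed.mrna_interval.end
                ]
                assert s_seg == _revcomp(m_seg)

    def test_oracle_equivalence(self, rng):
        for _ in range(60):
            s_res = random_rna(rng, int(rng.integers(10, 31)))
            m_res = random_rna(rng, int(rng.integers(10, 31)))
            seeds = find_seeds(
                rna("s", s_res), rna("m", m_res), SeedParams(report_maximal=True)
            )
            got_perfect = {
                (sd.srna_interval.start - 1, sd.mrna_interval.start - 1,
                 sd.srna_interval.length)
                for sd in seeds
                if sd.kind is SeedKind.SEVEN_BP
            }
            assert got_perfect == brute_force_perfect_duplexes(s_res, m_res)
            oracle_bulged = brute_force_bulged_duplexes(s_res, m_res)
            got_bulged = {
                (sd.srna_interval.start - 1, sd.srna_interval.length,
                 sd.mrna_interval.start - 1, sd.mrna_interval.length,
                 sd.gap_strand.value)
                for sd in seeds
                if sd.kind is SeedKind.SIX_GAP_TWO
            }
            # the scanner suppresses bulged hits lying inside a reported
            # perfect duplex; the oracle does not, so compare modulo that
            suppressed = {
                (si, sl, mi, ml, gs)
                for si, sl, mi, ml, gs in oracle_bulged
                if any(
                    ps <= si and si + sl - 1 <= ps + ln - 1
                    and pm <= mi and mi + ml - 1 <= pm + ln - 1
                    for ps, pm, ln in got_perfect
                )
            }
            assert got_bulged == oracle_bulged - suppressed


class TestOverlay:
    def test_positions_relative_to_motif(self):
        seeds = find_seeds(rna("srna", "G" * 7 + "C" * 30), rna("m", "C" * 7))
        motif = Interval("srna", 20, 36)
        (rec,) = map_seeds_to_regions(seeds, [motif])
        assert rec["position"] == "upstream"

    def test_overlapping_and_downstream(self):
        s = rna("srna", "C" * 24 + "G" * 7 + "C" * 4)
        seeds = find_seeds(s, rna("m", "C" * 7))
        assert [r["position"] for r in map_seeds_to_regions(seeds, [Interval("srna", 20, 40)])] == ["overlapping"]
        assert [r["position"] for r in map_seeds_to_regions(seeds, [Interval("srna", 1, 10)])] == ["downstream"]

    def test_seed_inside_hairpin_loop(self):
        # stem(5) | loop(7) holding the seed | stem(5)
        s = rna("srna", "GGGGG" + "AAAAAAA" + "CCCCC")
        structure = DotBracketStructure(
            seq_id="srna", brackets="(((((" + "......." + ")))))"
        )
        seeds = find_seeds(s, rna("m", "UUUUUUU"))
        recs = map_seeds_to_regions(seeds, [Interval("srna", 1, 3)], structure)
        assert recs and all(r["in_hairpin_loop"] for r in recs)

    def test_mismatched_ids_rejected(self):
        seeds = find_seeds(rna("a", "GGGGGGG"), rna("m", "CCCCCCC"))
        with pytest.raises(ValueError):
            map_seeds_to_regions(seeds, [Interval("other", 1, 5)])
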