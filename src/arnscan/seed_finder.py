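"""sRNA-mRNA seed complementarity search.

A seed is the minimal complementary element initiating sRNA-mRNA
pairing.  Here it is purely combinatorial: either seven consecutive
Watson-Crick base pairs, or six consecutive pairs followed — across a
single bulged nucleotide on one strand — by two further pairs.  Both
bulge strands and both reading orders (6+gap+2 and 2+gap+6 along the
sRNA) are searched, since duplex complementarity fixes neither.
G:U wobble pairing is off by default and available behind a flag.
Abasic residues ('0') never pair.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .seqio import Interval, RnaSequence, to_native

__all__ = [
    "SeedKind",
    "GapStrand",
    "SeedParams",
    "SeedMatch",
    "find_seeds",
    "map_seeds_to_regions",
]


class SeedKind(str, enum.Enum):
    SEVEN_BP = "7bp"
    SIX_GAP_TWO = "6+gap+2bp"


class GapStrand(str, enum.Enum):
    NONE = "none"
    SRNA = "srna"
    MRNA = "mrna"


_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


def _pairs(a: str, b: str, wobble: bool) -> bool:
    if (a, b) in _WC:
        return True
    return wobble and (a, b) in _WOBBLE


@dataclass(frozen=True)
class SeedParams:
    allow_wobble: bool = False
    report_maximal: bool = True


@dataclass(frozen=True)
class SeedMatch:
    """One complementary interval pair; intervals in native coordinates.

    ``pair_string`` renders the duplex: sRNA strand 5'->3' on top,
    mRNA strand 3'->5' below, '|' for pairs and '-' for the bulge.
    """

    srna_interval: Interval
    mrna_interval: Interval
    kind: SeedKind
    gap_strand: GapStrand
    pair_string: str


def _render(
    srna: str, mrna_rev: str, bulge_at: int | None, bulge_strand: GapStrand
) -> str:
    """Textual duplex; ``mrna_rev`` is the mRNA segment already reversed
    (3'->5'), ``bulge_at`` the 0-based index of the bulged residue on the
    bulged strand."""
    top, mid, bot = [], [], []
    i = j = 0
    while i < len(srna) or j < len(mrna_rev):
        if bulge_strand is GapStrand.SRNA and i == bulge_at and i < len(srna):
            top.append(srna[i]); mid.append("-"); bot.append(" ")
            i += 1
            bulge_at = None
            continue
        if bulge_strand is GapStrand.MRNA and j == bulge_at and j < len(mrna_rev):
            top.append(" "); mid.append("-"); bot.append(mrna_rev[j])
            j += 1
            bulge_at = None
            continue
        top.append(srna[i]); mid.append("|"); bot.append(mrna_rev[j])
        i += 1; j += 1
    return "".join(top) + "/" + "".join(mid) + "/" + "".join(bot)


def _perfect_duplexes(
    s: str, m: str, wobble: bool, min_len: int = 7
) -> list[tuple[int, int, int]]:
    """Maximal perfect antiparallel duplexes as (s_start, m_start, length),
    all 0-based; s[s_start] pairs m[m_start + length - 1].

    In an antiparallel duplex the sum of the paired indices is constant,
    so maximal duplexes are maximal runs along each anti-diagonal.
    """
    out = []
    ns, nm = len(s), len(m)
    for c in range(ns + nm - 1):
        i_lo = max(0, c - (nm - 1))
        i_hi = min(ns - 1, c)
        run = 0
        for i in range(i_lo, i_hi + 2):  # one step past the end flushes the run
            if i <= i_hi and _pairs(s[i], m[c - i], wobble):
                run += 1
            else:
                if run >= min_len:
                    i0, i1 = i - run, i - 1
                    out.append((i0, c - i1, run))
                run = 0
    return out


def find_seeds(
    srna: RnaSequence, mrna: RnaSequence, params: SeedParams | None = None
) -> list[SeedMatch]:
    """Enumerate all seed matches between one sRNA and one mRNA.

    With ``report_maximal`` (default) a seven-pair hit inside a longer
    perfect duplex is reported once, as the maximal duplex, and bulged
    hits fully contained in a reported perfect duplex are suppressed.
    """
    params = params or SeedParams()
    s, m = srna.residues, mrna.residues
    wob = params.allow_wobble
    matches: list[SeedMatch] = []

    perfect = _perfect_duplexes(s, m, wob, min_len=7)
    if not params.report_maximal:
        # expand to every minimal 7-pair window inside each maximal duplex
        expanded = []
        for si, mj, ln in perfect:
            for off in range(ln - 7 + 1):
                expanded.append((si + off, mj + ln - 7 - off, 7))
        perfect = expanded
    perfect_ivs = []
    for si, mj, ln in sorted(set(perfect)):
        s_iv = Interval(srna.id, to_native(srna, si + 1), to_native(srna, si + ln))
        m_iv = Interval(mrna.id, to_native(mrna, mj + 1), to_native(mrna, mj + ln))
        seg_s = s[si : si + ln]
        seg_m_rev = m[mj : mj + ln][::-1]
        matches.append(
            SeedMatch(
                srna_interval=s_iv,
                mrna_interval=m_iv,
                kind=SeedKind.SEVEN_BP,
                gap_strand=GapStrand.NONE,
                pair_string=_render(seg_s, seg_m_rev, None, GapStrand.NONE),
            )
        )
        perfect_ivs.append(((si, si + ln - 1), (mj, mj + ln - 1)))

    # bulged seeds: seg1 pairs, one bulged nt on one strand, seg2 pairs,
    # walking sRNA 5'->3' against mRNA 3'->5'
    seen: set[tuple] = set()
    for seg1, seg2 in ((6, 2), (2, 6)):
        for bulge_strand in (GapStrand.SRNA, GapStrand.MRNA):
            s_len = seg1 + seg2 + (1 if bulge_strand is GapStrand.SRNA else 0)
            m_len = seg1 + seg2 + (1 if bulge_strand is GapStrand.MRNA else 0)
            for si in range(len(s) - s_len + 1):
                for mj in range(len(m) - m_len + 1):
                    # mRNA is read 3'->5': sRNA si pairs mRNA mj+m_len-1
                    ok = True
                    for k in range(seg1):
                        if not _pairs(s[si + k], m[mj + m_len - 1 - k], wob):
                            ok = False
                            break
                    if not ok:
                        continue
                    s_off = seg1 + (1 if bulge_strand is GapStrand.SRNA else 0)
                    m_skip = seg1 + (1 if bulge_strand is GapStrand.MRNA else 0)
                    for k in range(seg2):
                        if not _pairs(
                            s[si + s_off + k], m[mj + m_len - 1 - m_skip - k], wob
                        ):
                            ok = False
                            break
                    if not ok:
                        continue
                    key = (si, s_len, mj, m_len, bulge_strand)
                    if key in seen:
                        continue
                    seen.add(key)
                    if params.report_maximal and any(
                        ps[0] <= si and si + s_len - 1 <= ps[1]
                        and pm[0] <= mj and mj + m_len - 1 <= pm[1]
                        for ps, pm in perfect_ivs
                    ):
                        continue
                    bulge_idx = seg1  # 0-based on the bulged strand's segment
                    seg_s = s[si : si + s_len]
                    seg_m_rev = m[mj : mj + m_len][::-1]
                    matches.append(
                        SeedMatch(
                            srna_interval=Interval(
                                srna.id,
                                to_native(srna, si + 1),
                                to_native(srna, si + s_len),
                            ),
                            mrna_interval=Interval(
                                mrna.id,
                                to_native(mrna, mj + 1),
                                to_native(mrna, mj + m_len),
                            ),
                            kind=SeedKind.SIX_GAP_TWO,
                            gap_strand=bulge_strand,
                            pair_string=_render(
                                seg_s, seg_m_rev, bulge_idx, bulge_strand
                            ),
                        )
                    )

    matches.sort(
        key=lambda sm: (
            sm.srna_interval.start,
            sm.mrna_interval.start,
            sm.kind.value,
            sm.gap_strand.value,
        )
    )
    return matches


def map_seeds_to_regions(
    seeds: list[SeedMatch],
    motif_regions: list,
    structure=None,
) -> list[dict]:
    """Classify each seed relative to the sRNA's motif regions and,
    optionally, its secondary structure.

    Returns one record per (seed, nearest relation): position is one of
    ``upstream`` / ``overlapping`` / ``downstream`` relative to each
    motif region; with a structure, ``in_hairpin_loop`` marks seeds whose
    sRNA interval lies inside a hairpin loop.
    """
    from .architecture import find_hairpins  # local import to avoid a cycle

    records = []
    loops = []
    if structure is not None:
        loops = [h.loop for h in find_hairpins(structure)]
    for seed in seeds:
        s_iv = seed.srna_interval
        for region in motif_regions:
            r_iv = getattr(region, "interval", region)
            if r_iv.seq_id != s_iv.seq_id:
                raise ValueError(
                    f"seed on {s_iv.seq_id!r} vs motif region on {r_iv.seq_id!r}"
                )
            if s_iv.overlaps(r_iv):
                position = "overlapping"
            elif s_iv.end < r_iv.start:
                position = "upstream"
            else:
                position = "downstream"
            rec = {
                "srna_id": s_iv.seq_id,
                "seed_start": s_iv.start,
                "seed_end": s_iv.end,
                "kind": seed.kind.value,
                "gap_strand": seed.gap_strand.value,
                "motif_start": r_iv.start,
                "motif_end": r_iv.end,
                "position": position,
            }
            if structure is not None:
                rec["in_hairpin_loop"] = any(
                    lp.start <= s_iv.start and s_iv.end <= lp.end for lp in loops
                )
            records.append(rec)
    return records
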