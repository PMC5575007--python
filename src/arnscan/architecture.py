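"""Motif-architecture mapping: secondary-structure context, 3' poly(U)
distance, mRNA 5' windows, bipartite motif spacing, and conservation of
motif positions across homolog alignments.

Several (ARN)_X-containing sRNAs share a modular build: the motif sits
largely unpaired between two stem-loops and 20-40 nt upstream of the
3' poly(U) tail of the Rho-independent terminator, so that the distal
(A-rich-binding) and proximal (U-rich-binding) faces of Hfq can be
engaged simultaneously.  This module quantifies those features given
externally predicted structures (dot-bracket), annotations and
alignments; it never computes a folding itself, but can emit Vienna
constraint strings that keep motif positions unpaired in an external
folding engine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from .pattern_engine import Element, is_arn_triplet
from .seqio import (
    Alignment,
    DotBracketStructure,
    Interval,
    RnaSequence,
    native_to_linear,
    to_native,
)

logger = logging.getLogger(__name__)

__all__ = [
    "HairpinElement",
    "MrnaWindow",
    "MotifContext",
    "ArchitectureReport",
    "find_hairpins",
    "motif_context",
    "poly_u_distance",
    "mrna_window",
    "bipartite_regions",
    "conservation_profile",
    "folding_constraints",
    "native_spacing",
]


@dataclass(frozen=True)
class HairpinElement:
    """An innermost stem-loop: 5' stem arm, loop, 3' stem arm (local
    1-based coordinates on the structure)."""

    stem5: Interval
    loop: Interval
    stem3: Interval


@dataclass(frozen=True)
class MotifContext:
    hairpin_5p: Optional[HairpinElement]
    hairpin_3p: Optional[HairpinElement]
    unpaired_fraction: float
    embraced: bool  # hairpins on both sides
    mostly_unpaired: bool  # >=90% of motif positions unpaired


@dataclass(frozen=True)
class MrnaWindow:
    gene_id: str
    utr_start: Optional[int]  # negative coordinate, None when unannotated
    window: Interval  # in signed mRNA numbering (no position 0)


@dataclass(frozen=True)
class ArchitectureReport:
    motif_region: Interval
    context: Optional[MotifContext]
    poly_u_distance: Optional[int]
    seed_overlay: tuple
    conservation_persistence: Optional[float]


# ---------------------------------------------------------------------------
# secondary structure
# ---------------------------------------------------------------------------

def find_hairpins(structure: DotBracketStructure) -> list[HairpinElement]:
    """All innermost hairpins: maximal contiguously stacked helices whose
    enclosed region contains no brackets."""
    pairs = structure.pair_table()
    br = structure.brackets
    hairpins = []
    n = len(br)
    for i in range(1, n + 1):
        j = pairs.get(i)
        if j is None or j < i:
            continue
        enclosed = br[i : j - 1]  # positions i+1 .. j-1
        if "(" in enclosed or ")" in enclosed:
            continue
        # (i, j) closes a hairpin loop; extend the helix outward while
        # pairs stack contiguously
        k = 0
        while pairs.get(i - k - 1) == j + k + 1:
            k += 1
        hairpins.append(
            HairpinElement(
                stem5=Interval(structure.seq_id, i - k, i),
                loop=Interval(structure.seq_id, i + 1, j - 1),
                stem3=Interval(structure.seq_id, j, j + k),
            )
        )
    hairpins.sort(key=lambda h: h.stem5.start)
    return hairpins


def motif_context(
    region: Interval, structure: DotBracketStructure, offset: int = 1
) -> MotifContext:
    """Structural context of a motif region.

    ``region`` is given in native coordinates; ``offset`` is the native
    coordinate of the structure's first position (matching the paired
    sequence).  Hairpin coordinates in the result stay local.
    """
    lo = native_to_linear(region.start) - native_to_linear(offset) + 1
    hi = native_to_linear(region.end) - native_to_linear(offset) + 1
    if lo < 1 or hi > len(structure):
        raise ValueError(f"region {region.start}-{region.end} outside structure")
    hairpins = find_hairpins(structure)
    up = [h for h in hairpins if h.stem3.end < lo]
    down = [h for h in hairpins if h.stem5.start > hi]
    h5 = up[-1] if up else None
    h3 = down[0] if down else None
    segment = structure.brackets[lo - 1 : hi]
    unpaired = segment.count(".") / len(segment)
    return MotifContext(
        hairpin_5p=h5,
        hairpin_3p=h3,
        unpaired_fraction=unpaired,
        embraced=h5 is not None and h3 is not None,
        mostly_unpaired=unpaired >= 0.9,
    )


# ---------------------------------------------------------------------------
# poly(U) tail
# ---------------------------------------------------------------------------

def poly_u_distance(
    seq: RnaSequence,
    region: Interval,
    min_u_run: int = 4,
    search_window: int = 15,
) -> Optional[int]:
    """Distance (nt) from the region end to the first U of the
    3'-terminal poly(U) run, or None without a qualifying run.

    The tail is operationalized as the 3'-most run of at least
    ``min_u_run`` consecutive U residues overlapping the 3'-terminal
    ``search_window`` nucleotides.
    """
    res = seq.residues
    n = len(res)
    window_lo = max(1, n - search_window + 1)
    runs = []
    i = 0
    while i < n:
        if res[i] == "U":
            j = i
            while j < n and res[j] == "U":
                j += 1
            if j - i >= min_u_run and j >= window_lo:  # run overlaps the window
                runs.append((i + 1, j))  # local 1-based [start, end]
            i = j
        else:
            i += 1
    if not runs:
        return None
    tail_start_local = runs[-1][0]
    tail_start = to_native(seq, tail_start_local)
    dist = native_to_linear(tail_start) - native_to_linear(region.end) - 1
    return dist if dist >= 0 else None


# ---------------------------------------------------------------------------
# mRNA windows
# ---------------------------------------------------------------------------

def mrna_window(
    seq: RnaSequence,
    cds_start: int,
    utr_start: Optional[int] = None,
    gene_id: Optional[str] = None,
    downstream_nt: int = 80,
) -> tuple[MrnaWindow, RnaSequence]:
    """Extract the analysis window spanning the 5' UTR and the first
    ``downstream_nt`` nucleotides of the coding sequence.

    ``cds_start`` is the local 1-based position of the start codon's
    first nucleotide; ``utr_start`` is the annotated 5' UTR start as a
    negative coordinate (e.g. -120), defaulting to -80 when the UTR is
    unannotated.  The windowed sequence carries a negative offset so all
    reporting uses signed mRNA numbering without position 0.
    """
    if not (1 <= cds_start <= len(seq)):
        raise ValueError(f"cds_start {cds_start} outside {seq.id!r}")
    if utr_start is not None and utr_start >= 0:
        raise ValueError("utr_start must be a negative coordinate")
    upstream = -(utr_start if utr_start is not None else -80)
    lo = cds_start - upstream
    hi = cds_start + downstream_nt - 1
    if lo < 1:
        logger.warning(
            "window for %s clipped at sequence start (wanted %d upstream nt, "
            "have %d)", seq.id, upstream, cds_start - 1
        )
        lo = max(1, lo)
    if hi > len(seq):
        logger.warning("window for %s clipped at sequence end", seq.id)
        hi = len(seq)
    actual_up = cds_start - lo
    offset = -actual_up if actual_up > 0 else 1
    windowed = RnaSequence(
        id=gene_id or seq.id,
        residues=seq.residues[lo - 1 : hi],
        offset=offset,
    )
    window_iv = Interval(
        windowed.id,
        to_native(windowed, 1),
        to_native(windowed, len(windowed)),
    )
    return (
        MrnaWindow(
            gene_id=windowed.id,
            utr_start=utr_start,
            window=window_iv,
        ),
        windowed,
    )


# ---------------------------------------------------------------------------
# bipartite motif spacing
# ---------------------------------------------------------------------------

def native_spacing(end_a: int, start_b: int) -> int:
    """Number of nucleotides strictly between two native coordinates,
    honouring the missing position 0."""
    return native_to_linear(start_b) - native_to_linear(end_a) - 1


def bipartite_regions(
    regions: list[Interval],
    band: tuple[int, int] = (40, 80),
) -> list[dict]:
    """Spacing report for consecutive motif-region pairs in one mRNA
    window; pairs whose spacing falls within ``band`` are flagged as
    candidate bipartite motifs (two sub-elements that may fold together
    onto one Hfq distal face)."""
    ivs = sorted((getattr(r, "interval", r) for r in regions), key=lambda r: native_to_linear(r.start))
    out = []
    for a, b in zip(ivs, ivs[1:]):
        spacing = native_spacing(a.end, b.start)
        out.append(
            {
                "first_start": a.start,
                "first_end": a.end,
                "second_start": b.start,
                "second_end": b.end,
                "spacing_nt": spacing,
                "candidate_bipartite": band[0] <= spacing <= band[1],
            }
        )
    return out


# ---------------------------------------------------------------------------
# conservation
# ---------------------------------------------------------------------------

def _ungapped_to_column(row: str) -> dict[int, int]:
    """Map ungapped 1-based positions of a row to alignment columns."""
    mapping = {}
    pos = 0
    for col, ch in enumerate(row, start=1):
        if ch != "-":
            pos += 1
            mapping[pos] = col
    return mapping


_SITE_CLASS = {0: frozenset("A"), 1: frozenset("AG")}  # A-site, R-site


def conservation_profile(
    alignment: Alignment,
    reference_id: str,
    region: Interval,
    tiling: Optional[list[tuple[Element, int, int]]] = None,
) -> dict:
    """Per-column conservation of the A- and R-site positions of a motif
    region, plus the fraction of rows in which the motif persists.

    ``region`` is in ungapped reference coordinates (local, 1-based).
    ``tiling`` is the element breakdown of the motif (as produced by the
    scanner, in the same local coordinates); without one, the region is
    read as consecutive triplets from its start, which is exact for
    gap-free, NF-free motifs.

    A column where any non-reference row carries a gap is flagged;
    per-column conservation is computed over the non-gap rows, and rows
    with a gap at any A/R column are excluded from the persistence
    denominator.
    """
    ref_row = alignment.row(reference_id)
    col_of = _ungapped_to_column(ref_row)
    if region.end > max(col_of):
        raise ValueError("region extends beyond the ungapped reference")

    # A/R site positions (ungapped reference coords) with their classes
    sites: list[tuple[int, frozenset]] = []
    if tiling is not None:
        for elem, a, b in tiling:
            if elem is Element.ARN:
                sites.append((a, _SITE_CLASS[0]))
                sites.append((a + 1, _SITE_CLASS[1]))
    else:
        p = region.start
        while p + 2 <= region.end:
            sites.append((p, _SITE_CLASS[0]))
            sites.append((p + 1, _SITE_CLASS[1]))
            p += 3

    others = [seq for rid, seq in alignment.rows]
    columns = []
    for pos, allowed in sites:
        col = col_of[pos]
        residues = [row[col - 1] for row in others]
        non_gap = [r for r in residues if r != "-"]
        match = sum(r in allowed for r in non_gap)
        columns.append(
            {
                "ref_position": pos,
                "column": col,
                "site": "A" if allowed == _SITE_CLASS[0] else "R",
                "conservation": match / len(non_gap) if non_gap else 0.0,
                "flagged_gap": len(non_gap) < len(residues),
            }
        )

    evaluable = satisfied = 0
    for rid, row in alignment.rows:
        residues = [row[col_of[pos] - 1] for pos, _ in sites]
        if "-" in residues:
            continue
        evaluable += 1
        if all(r in allowed for r, (_, allowed) in zip(residues, sites)):
            satisfied += 1
    persistence = satisfied / evaluable if evaluable else 0.0
    return {
        "columns": columns,
        "persistence": persistence,
        "n_rows": len(alignment.rows),
        "n_rows_evaluated": evaluable,
    }


# ---------------------------------------------------------------------------
# folding constraints
# ---------------------------------------------------------------------------

def folding_constraints(
    regions: Interval | list[Interval], seq_len: int
) -> str:
    """Vienna-style constraint line keeping motif positions unpaired:
    'x' at masked (local 1-based) positions, '.' elsewhere."""
    if isinstance(regions, Interval):
        regions = [regions]
    line = ["."] * seq_len
    for r in regions:
        iv = getattr(r, "interval", r)
        if iv.start < 1 or iv.end > seq_len:
            raise ValueError(f"region {iv.start}-{iv.end} outside length {seq_len}")
        for p in range(iv.start, iv.end + 1):
            line[p - 1] = "x"
    return "".join(line)
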