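"""Refined (ARN)_X motif scanning: maximal-match enumeration, overlap
merging and per-cohort reporting.

The refined motif definition requires at least four ARN triplets within
a single match spanning at most 20 nucleotides, tolerating up to two
non-adjacent non-functional triplets and up to two separated single
gaps; every match begins and ends with an ARN triplet.  Longer motifs
(such as the 28-nt OxyS element at positions 59-86) arise by merging
overlapping <=20-nt matches, mirroring how overlapping pattern hits were
collapsed into single reported regions.

The scanner performs a depth-first extension over element tilings from
each candidate start (a position opening an ARN triplet), records every
valid match interval, and reports only maximal intervals — intervals not
strictly contained in another valid match — since merging makes
sub-matches redundant.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .pattern_engine import Element, is_arn_triplet
from .seqio import Interval, RnaSequence, to_native

__all__ = [
    "ScanParams",
    "MotifMatch",
    "MotifRegion",
    "ScanReport",
    "find_matches",
    "merge_matches",
    "scan_set",
]

HISTOGRAM_BINS = ("0", "1", "2", "3", "4", "5+")


@dataclass(frozen=True)
class ScanParams:
    """Knobs of the refined motif definition.

    ``n_arn_min`` may be relaxed (e.g. to 3) when scanning mRNA 5'
    windows, where shorter (ARN)_X regions are the norm.
    """

    n_arn_min: int = 4
    max_nf: int = 2
    max_gaps: int = 2
    window_nt: int = 20

    def __post_init__(self) -> None:
        if self.n_arn_min < 1 or self.max_nf < 0 or self.max_gaps < 0:
            raise ValueError("invalid scan parameters")
        if self.window_nt < 3 * self.n_arn_min:
            raise ValueError("window cannot hold the required ARN triplets")


@dataclass(frozen=True)
class MotifMatch:
    """One maximal tiling match, in native coordinates."""

    interval: Interval
    elements: tuple[tuple[Element, int, int], ...]  # (class, start, end) native
    n_arn: int
    n_nonfunctional: int
    n_gaps: int

    def element_string(self) -> str:
        return "".join(
            {"ARN": "A", "NF": "N", "GAP": "g"}[e.value] for e, _, _ in self.elements
        )


@dataclass(frozen=True)
class MotifRegion:
    """A merged run of overlapping matches — the reported motif unit."""

    interval: Interval
    support: tuple[MotifMatch, ...]
    max_arn: int

    @property
    def n_nonfunctional(self) -> int:
        return max(m.n_nonfunctional for m in self.support)

    @property
    def n_gaps(self) -> int:
        return max(m.n_gaps for m in self.support)


@dataclass
class ScanReport:
    """Per-sequence merged regions plus the cohort histogram."""

    regions: dict[str, list[MotifRegion]] = field(default_factory=dict)
    params: ScanParams = field(default_factory=ScanParams)

    @property
    def histogram(self) -> dict[str, int]:
        counts = Counter()
        for regs in self.regions.values():
            n = len(regs)
            counts[str(n) if n < 5 else "5+"] += 1
        return {b: counts.get(b, 0) for b in HISTOGRAM_BINS}

    @property
    def n_with_motif(self) -> int:
        return sum(1 for regs in self.regions.values() if regs)

    def to_tsv(self) -> str:
        lines = ["seq_id\tn_regions\tregions"]
        for sid in sorted(self.regions):
            regs = self.regions[sid]
            spans = ",".join(f"{r.interval.start}-{r.interval.end}" for r in regs)
            lines.append(f"{sid}\t{len(regs)}\t{spans or '-'}")
        lines.append("")
        lines.append("# histogram of regions per sequence")
        for b, n in self.histogram.items():
            lines.append(f"# {b}\t{n}")
        return "\n".join(lines) + "\n"


def _tilings_from(
    residues: str, start: int, params: ScanParams
) -> list[tuple[tuple[Element, int, int], ...]]:
    """All complete element tilings beginning with an ARN triplet at
    ``start`` (local 1-based) that satisfy the match constraints and end
    on an ARN triplet."""
    n = len(residues)
    window_end = start + params.window_nt - 1
    results: list[tuple[tuple[Element, int, int], ...]] = []

    def extend(path: list[tuple[Element, int, int]], n_arn: int, n_nf: int, n_gaps: int):
        last_elem, _, last_end = path[-1]
        if last_elem is Element.ARN and n_arn >= params.n_arn_min:
            results.append(tuple(path))
        cursor = last_end + 1
        # try ARN / NF triplet
        if cursor + 2 <= min(n, window_end):
            triplet = residues[cursor - 1 : cursor + 2]
            if is_arn_triplet(triplet):
                path.append((Element.ARN, cursor, cursor + 2))
                extend(path, n_arn + 1, n_nf, n_gaps)
                path.pop()
            if n_nf < params.max_nf and last_elem is not Element.NF:
                path.append((Element.NF, cursor, cursor + 2))
                extend(path, n_arn, n_nf + 1, n_gaps)
                path.pop()
        # try single gap
        if (
            cursor <= min(n, window_end)
            and n_gaps < params.max_gaps
            and last_elem is not Element.GAP
        ):
            path.append((Element.GAP, cursor, cursor))
            extend(path, n_arn, n_nf, n_gaps + 1)
            path.pop()

    if start + 2 <= n and is_arn_triplet(residues[start - 1 : start + 2]):
        extend([(Element.ARN, start, start + 2)], 1, 0, 0)
    return results


_ELEM_ORDER = {Element.ARN: "A", Element.GAP: "g", Element.NF: "N"}


def _tiling_key(tiling: tuple[tuple[Element, int, int], ...]) -> tuple:
    n_arn = sum(e is Element.ARN for e, _, _ in tiling)
    n_gaps = sum(e is Element.GAP for e, _, _ in tiling)
    elem_str = "".join(_ELEM_ORDER[e] for e, _, _ in tiling)
    # prefer more ARN, then fewer gaps, then lexicographically earliest
    return (-n_arn, n_gaps, elem_str)


def find_matches(seq: RnaSequence, params: ScanParams | None = None) -> list[MotifMatch]:
    """Enumerate every maximal refined-pattern match on one sequence.

    A match is maximal when no other valid match strictly contains its
    interval.  Among alternative tilings of the same interval the one
    with the most ARN triplets, then the fewest gaps, then the
    lexicographically earliest element string is reported; the interval
    itself never depends on this tie-break.
    """
    params = params or ScanParams()
    if len(seq) < 3 * params.n_arn_min:
        return []
    residues = seq.residues
    # interval (local start, local end) -> best tiling
    best: dict[tuple[int, int], tuple[tuple[Element, int, int], ...]] = {}
    for start in range(1, len(residues) - 1):
        for tiling in _tilings_from(residues, start, params):
            end = tiling[-1][2]
            key = (start, end)
            if key not in best or _tiling_key(tiling) < _tiling_key(best[key]):
                best[key] = tiling

    intervals = sorted(best)
    maximal = [
        iv
        for iv in intervals
        if not any(
            other != iv and other[0] <= iv[0] and other[1] >= iv[1]
            for other in intervals
        )
    ]
    matches = []
    for s, e in maximal:
        tiling = best[(s, e)]
        native_elems = tuple(
            (elem, to_native(seq, a), to_native(seq, b)) for elem, a, b in tiling
        )
        matches.append(
            MotifMatch(
                interval=Interval(seq.id, to_native(seq, s), to_native(seq, e)),
                elements=native_elems,
                n_arn=sum(e_ is Element.ARN for e_, _, _ in tiling),
                n_nonfunctional=sum(e_ is Element.NF for e_, _, _ in tiling),
                n_gaps=sum(e_ is Element.GAP for e_, _, _ in tiling),
            )
        )
    matches.sort(key=lambda m: (m.interval.start, m.interval.end))
    return matches


def merge_matches(matches: list[MotifMatch]) -> list[MotifRegion]:
    """Union overlapping match intervals (>=1 nt shared) into regions.

    Abutting (book-ended) matches are kept separate: the reported motif
    unit is the union of *overlapping* pattern hits only.
    """
    if not matches:
        return []
    seq_ids = {m.interval.seq_id for m in matches}
    if len(seq_ids) != 1:
        raise ValueError(f"matches span multiple sequences: {sorted(seq_ids)}")
    ordered = sorted(matches, key=lambda m: (m.interval.start, m.interval.end))
    regions: list[MotifRegion] = []
    cluster = [ordered[0]]
    hi = ordered[0].interval.end
    sid = ordered[0].interval.seq_id

    def flush():
        regions.append(
            MotifRegion(
                interval=Interval(sid, cluster[0].interval.start, hi),
                support=tuple(cluster),
                max_arn=max(m.n_arn for m in cluster),
            )
        )

    for m in ordered[1:]:
        if m.interval.start <= hi:  # >=1 nt overlap
            cluster.append(m)
            hi = max(hi, m.interval.end)
        else:
            flush()
            cluster = [m]
            hi = m.interval.end
    flush()
    return regions


def scan_set(
    seqs: list[RnaSequence], params: ScanParams | None = None
) -> ScanReport:
    """Scan a sequence cohort and tabulate regions per sequence."""
    params = params or ScanParams()
    if not seqs:
        raise ValueError("no sequences to scan")
    ids = [s.id for s in seqs]
    dupes = [i for i, c in Counter(ids).items() if c > 1]
    if dupes:
        raise ValueError(f"duplicate sequence ids: {dupes}")
    report = ScanReport(params=params)
    for seq in seqs:
        report.regions[seq.id] = merge_matches(find_matches(seq, params))
    return report
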