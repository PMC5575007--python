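"""Generation of permuted (ARN)_X pattern layouts and triplet semantics.

The Hfq distal site binds RNA as repeated three-nucleotide units: an
A-site that accepts only adenine, an R-site that accepts a purine
(A or G), and an N-site whose base is flipped away from the protein and
is unconstrained.  A search pattern for such motifs is an ordered tiling
of three element kinds:

* ``ARN``  — a triplet satisfying the A/R constraints (3 nt),
* ``NF``   — a tolerated non-functional triplet, i.e. any 3-mer (3 nt),
* ``GAP``  — a single unassigned spacer nucleotide (1 nt).

Layouts always begin and end with an ARN element, and neither two NF
triplets nor two gaps may directly abut.  ``enumerate_layouts`` produces
every distinct layout consistent with a pattern definition by permuting
the positions of the non-ARN elements — the explorative machinery from
which the refined motif definition (>=4 ARN triplets within 20 nt,
<=2 NF triplets, <=2 single gaps) was distilled.  Note the identity
4*3 + 2*3 + 2*1 = 20: the refined window is exactly saturable.
"""

from __future__ import annotations

import enum
import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "Element",
    "AmbiguityClass",
    "PatternDefinition",
    "PatternLayout",
    "is_arn_triplet",
    "classify_triplet",
    "enumerate_layouts",
    "layouts_for_counts",
    "layout_matches_at",
    "load_pattern_config",
    "write_layout_table",
]


class Element(str, enum.Enum):
    ARN = "ARN"
    NF = "NF"
    GAP = "GAP"

    @property
    def span(self) -> int:
        return 1 if self is Element.GAP else 3


class AmbiguityClass(str, enum.Enum):
    """The families of pattern definitions explored, in increasing
    permissiveness."""

    CONSERVATIVE = "CONSERVATIVE"      # consecutive ARN triplets only
    NF_TRIPLETS = "NF_TRIPLETS"        # non-functional triplets, no gaps
    GAPS_ADJACENT = "GAPS_ADJACENT"    # single gaps next to ARN triplets
    GAPS_ANYWHERE = "GAPS_ANYWHERE"    # single gaps anywhere inside
    COMBINED = "COMBINED"              # NF triplets and gaps together


# A-site: adenine only.  R-site: purine.  N-site: any base, and the only
# site where an abasic residue ('0') is tolerated, since that base points
# away from the protein (the '0'-substituted probes delete N-site bases).
_A_SITE = frozenset("A")
_R_SITE = frozenset("AG")
_N_SITE = frozenset("ACGU0")


def is_arn_triplet(triplet: str) -> bool:
    """True iff a 3-mer satisfies the distal-site A/R/N constraints."""
    if len(triplet) != 3:
        return False
    return (
        triplet[0] in _A_SITE
        and triplet[1] in _R_SITE
        and triplet[2] in _N_SITE
    )


def classify_triplet(triplet: str) -> Element:
    return Element.ARN if is_arn_triplet(triplet) else Element.NF


@dataclass(frozen=True)
class PatternLayout:
    """One ordered tiling of ARN / NF / GAP elements."""

    elements: tuple[Element, ...]

    def __post_init__(self) -> None:
        elems = self.elements
        if not elems:
            raise ValueError("empty layout")
        if elems[0] is not Element.ARN or elems[-1] is not Element.ARN:
            raise ValueError("layouts must begin and end with an ARN element")
        for a, b in zip(elems, elems[1:]):
            if a is b and a is not Element.ARN:
                raise ValueError(f"two adjacent {a.value} elements")

    @property
    def n_arn(self) -> int:
        return sum(e is Element.ARN for e in self.elements)

    @property
    def n_nf(self) -> int:
        return sum(e is Element.NF for e in self.elements)

    @property
    def n_gaps(self) -> int:
        return sum(e is Element.GAP for e in self.elements)

    @property
    def span_nt(self) -> int:
        return sum(e.span for e in self.elements)

    def element_string(self) -> str:
        """Compact rendering: A = ARN, N = NF, g = GAP."""
        return "".join(
            {"ARN": "A", "NF": "N", "GAP": "g"}[e.value] for e in self.elements
        )


@dataclass(frozen=True)
class PatternDefinition:
    """Counts and window bounds defining one pattern family."""

    n_arn: int = 4
    max_nf: int = 2
    max_gaps: int = 2
    max_span_nt: int = 20
    ambiguity_class: AmbiguityClass = AmbiguityClass.COMBINED

    def __post_init__(self) -> None:
        if self.n_arn < 1:
            raise ValueError("n_arn must be >= 1")
        if self.ambiguity_class is AmbiguityClass.CONSERVATIVE and (
            self.max_nf or self.max_gaps
        ):
            raise ValueError("CONSERVATIVE definitions admit no NF or gaps")


def _layout_ok(elems: tuple[Element, ...]) -> bool:
    if elems[0] is not Element.ARN or elems[-1] is not Element.ARN:
        return False
    return all(
        not (a is b and a is not Element.ARN) for a, b in zip(elems, elems[1:])
    )


def _class_ok(elems: tuple[Element, ...], cls: AmbiguityClass) -> bool:
    has_nf = Element.NF in elems
    has_gap = Element.GAP in elems
    if cls is AmbiguityClass.CONSERVATIVE:
        return not has_nf and not has_gap
    if cls is AmbiguityClass.NF_TRIPLETS:
        return not has_gap
    if cls in (AmbiguityClass.GAPS_ADJACENT, AmbiguityClass.GAPS_ANYWHERE):
        if has_nf:
            return False
        if cls is AmbiguityClass.GAPS_ADJACENT:
            # every gap must directly neighbour an ARN triplet
            for i, e in enumerate(elems):
                if e is Element.GAP:
                    left = elems[i - 1] if i else None
                    right = elems[i + 1] if i + 1 < len(elems) else None
                    if left is not Element.ARN and right is not Element.ARN:
                        return False
        return True
    return True  # COMBINED


def layouts_for_counts(n_arn: int, n_nf: int, n_gaps: int) -> list[PatternLayout]:
    """Every distinct valid layout with exactly the given element counts,
    in deterministic lexicographic order of the element string."""
    total = n_arn + n_nf + n_gaps
    found = []
    # enumerate multiset permutations via combinations of slot indices
    slots = range(total)
    for nf_pos in itertools.combinations(slots, n_nf):
        remaining = [i for i in slots if i not in nf_pos]
        for gap_pos in itertools.combinations(remaining, n_gaps):
            elems = tuple(
                Element.NF
                if i in nf_pos
                else Element.GAP
                if i in gap_pos
                else Element.ARN
                for i in slots
            )
            if _layout_ok(elems):
                found.append(PatternLayout(elems))
    found.sort(key=lambda l: l.element_string())
    return found


def enumerate_layouts(defn: PatternDefinition) -> list[PatternLayout]:
    """All distinct layouts with exactly ``defn.n_arn`` ARN triplets, up to
    the definition's NF/gap budgets, within the span bound, filtered by the
    ambiguity class; deduplicated and lexicographically ordered."""
    if defn.n_arn < 2 and (defn.max_nf or defn.max_gaps):
        logger.warning(
            "n_arn=%d cannot host interior NF/GAP elements (boundary rule); "
            "returning the bare layouts only",
            defn.n_arn,
        )
    seen: set[tuple[Element, ...]] = set()
    out: list[PatternLayout] = []
    for n_nf in range(defn.max_nf + 1):
        for n_gaps in range(defn.max_gaps + 1):
            for layout in layouts_for_counts(defn.n_arn, n_nf, n_gaps):
                if layout.span_nt > defn.max_span_nt:
                    continue
                if not _class_ok(layout.elements, defn.ambiguity_class):
                    continue
                if layout.elements not in seen:
                    seen.add(layout.elements)
                    out.append(layout)
    out.sort(key=lambda l: l.element_string())
    return out


def layout_matches_at(
    layout: PatternLayout, residues: str, pos: int
) -> list[tuple[Element, int, int]] | None:
    """Tile ``layout`` against ``residues`` starting at local 1-based
    ``pos``.

    Returns the element coordinate breakdown ``[(element, start, end), ...]``
    on success, ``None`` otherwise (including out-of-range positions).
    GAP slots consume one residue of any identity; NF slots consume any
    3-mer, even one that happens to satisfy the ARN constraints.
    """
    if pos < 1 or pos + layout.span_nt - 1 > len(residues):
        return None
    coords: list[tuple[Element, int, int]] = []
    cursor = pos
    for elem in layout.elements:
        end = cursor + elem.span - 1
        if elem is Element.ARN and not is_arn_triplet(residues[cursor - 1 : end]):
            return None
        coords.append((elem, cursor, end))
        cursor = end + 1
    return coords


# ---------------------------------------------------------------------------
# config / export plumbing
# ---------------------------------------------------------------------------

def load_pattern_config(path: str | Path) -> PatternDefinition:
    """Read a pattern definition from a YAML config file.

    Recognised keys: n_arn_min, max_nonfunctional, max_gaps, window_nt,
    ambiguity_class.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return PatternDefinition(
        n_arn=int(raw.get("n_arn_min", 4)),
        max_nf=int(raw.get("max_nonfunctional", 2)),
        max_gaps=int(raw.get("max_gaps", 2)),
        max_span_nt=int(raw.get("window_nt", 20)),
        ambiguity_class=AmbiguityClass(raw.get("ambiguity_class", "COMBINED")),
    )


def write_layout_table(layouts: Iterable[PatternLayout], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("elements\tn_arn\tn_nf\tn_gaps\tspan_nt\n")
        for l in layouts:
            fh.write(
                f"{l.element_string()}\t{l.n_arn}\t{l.n_nf}\t{l.n_gaps}\t{l.span_nt}\n"
            )
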