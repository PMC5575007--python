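"""Synthetic sequence generation with known ground truth.

Every downstream stage (motif scanning, seed search, architecture
mapping, conservation profiling) is exercisable on generated data whose
planted features are recorded exactly, so recovery can be asserted
without any external sequence resource.

The generator emulates what the analysis assumes about real molecules:

* background RNA of configurable base composition, by default with the
  adenine frequency depressed to 0.2 (A-rich backgrounds breed spurious
  (ARN)_X hits; measuring that false-positive behaviour via
  :func:`shuffle_null` is itself a supported study output);
* planted (ARN)_X motifs assembled from a randomly chosen valid layout,
  with A preferred at the R-site (default 0.8, matching the observed
  bias) and unconstrained N-site bases;
* sRNAs with the shared modular architecture: stem-loop | motif |
  stem-loop | spacer | 3' poly(U), the spacer drawn from the observed
  20-40 nt band, with optional seed sequences embedded in the loops;
* homolog alignments in which motif A/R columns can mutate at a reduced
  rate relative to background (conservation of functional positions).

All randomness flows through integer-seeded ``numpy`` generators; equal
seeds give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .pattern_engine import Element, PatternLayout, is_arn_triplet, layouts_for_counts
from .seqio import Alignment, DotBracketStructure, Interval, RnaSequence

__all__ = [
    "MotifSpec",
    "SrnaArchitectureSpec",
    "GroundTruth",
    "plant_motif",
    "make_srna",
    "shuffle_null",
    "make_alignment",
]

_BASES = "ACGU"
DEFAULT_BACKGROUND = {"A": 0.2, "C": 0.27, "G": 0.27, "U": 0.26}
_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class MotifSpec:
    """Composition of a planted (ARN)_X motif."""

    n_arn: int = 4
    n_nf: int = 0
    n_gaps: int = 0
    p_a_at_r: float = 0.8
    n_base_distribution: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if not (0 <= self.n_nf <= 2 and 0 <= self.n_gaps <= 2):
            raise ValueError("n_nf and n_gaps must be within 0..2")
        if self.n_arn < 2 and (self.n_nf or self.n_gaps):
            raise ValueError("interior elements need at least 2 boundary ARN triplets")
        if abs(sum(self.n_base_distribution) - 1.0) > 1e-9:
            raise ValueError("n_base_distribution must sum to 1")

    @property
    def span_nt(self) -> int:
        return 3 * self.n_arn + 3 * self.n_nf + self.n_gaps


@dataclass(frozen=True)
class SrnaArchitectureSpec:
    """Modular sRNA layout: stem-loop | motif | spacer | poly(U) tail,
    with a second stem-loop embedded inside the spacer so the motif is
    embraced by hairpins on both sides.

    ``spacer_to_poly_u`` is the full motif-end to first-tail-U distance
    (the observed 20-40 nt band); it must be able to contain the 3'
    stem-loop."""

    stem5_len: int = 6
    loop5_len: int = 7
    motif: MotifSpec = field(default_factory=MotifSpec)
    stem3_len: int = 6
    loop3_len: int = 7
    spacer_to_poly_u: Optional[int] = None  # None: drawn uniformly 20..40
    poly_u_len: int = 6
    seed_5p: Optional[str] = None  # embedded in the 5' loop
    seed_3p: Optional[str] = None  # embedded in the 3' loop

    def __post_init__(self) -> None:
        if self.poly_u_len < 4:
            raise ValueError("poly(U) tail must be at least 4 nt")
        if self.seed_5p and len(self.seed_5p) > self.loop5_len:
            raise ValueError("5' seed longer than the 5' loop")
        if self.seed_3p and len(self.seed_3p) > self.loop3_len:
            raise ValueError("3' seed longer than the 3' loop")
        if self.spacer_to_poly_u is not None and self.spacer_to_poly_u < 0:
            raise ValueError("spacer must be non-negative")


@dataclass
class GroundTruth:
    """Planted features of one generated sequence (local 1-based)."""

    seq_id: str
    motif_intervals: list[Interval] = field(default_factory=list)
    motif_layout: Optional[PatternLayout] = None
    seed_intervals: list[Interval] = field(default_factory=list)
    hairpin_intervals: list[Interval] = field(default_factory=list)
    poly_u_spacing: Optional[int] = None


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _draw(rng: np.random.Generator, length: int, composition: dict[str, float]) -> str:
    bases = list(composition)
    probs = np.array([composition[b] for b in bases], dtype=float)
    probs = probs / probs.sum()
    return "".join(rng.choice(bases, size=length, p=probs)) if length else ""


def _motif_sequence(
    spec: MotifSpec, rng: np.random.Generator
) -> tuple[str, PatternLayout]:
    layouts = layouts_for_counts(spec.n_arn, spec.n_nf, spec.n_gaps)
    if not layouts:
        raise ValueError(
            f"no valid layout with {spec.n_arn} ARN, {spec.n_nf} NF, "
            f"{spec.n_gaps} gaps"
        )
    layout = layouts[rng.integers(len(layouts))]
    chunks = []
    for elem in layout.elements:
        if elem is Element.ARN:
            r = "A" if rng.random() < spec.p_a_at_r else "G"
            n = rng.choice(list(_BASES), p=np.array(spec.n_base_distribution))
            chunks.append("A" + r + str(n))
        elif elem is Element.NF:
            while True:  # any 3-mer failing the A/R constraints
                t = "".join(rng.choice(list("CGU"), size=3))
                if not is_arn_triplet(t):
                    break
            chunks.append(t)
        else:  # GAP: one spacer nucleotide, non-A to keep the plant tight
            chunks.append(str(rng.choice(list("CGU"))))
    return "".join(chunks), layout


def plant_motif(
    spec: MotifSpec,
    background_len: int,
    rng_seed: int | np.random.Generator,
    seq_id: str = "synthetic",
    background: dict[str, float] | None = None,
) -> tuple[RnaSequence, GroundTruth]:
    """Embed one valid (ARN)_X motif in random background.

    ``background_len`` is the total output length; the planted interval
    is placed uniformly at random and recorded in the ground truth.
    """
    rng = _rng(rng_seed)
    comp = background or DEFAULT_BACKGROUND
    motif_seq, layout = _motif_sequence(spec, rng)
    if background_len < len(motif_seq) + 6:
        raise ValueError(
            f"background_len {background_len} too short for a "
            f"{len(motif_seq)}-nt motif plus flanks"
        )
    start = int(rng.integers(1, background_len - len(motif_seq) + 2))
    left = _draw(rng, start - 1, comp)
    right = _draw(rng, background_len - len(motif_seq) - (start - 1), comp)
    seq = RnaSequence(id=seq_id, residues=left + motif_seq + right)
    truth = GroundTruth(
        seq_id=seq_id,
        motif_intervals=[Interval(seq_id, start, start + len(motif_seq) - 1)],
        motif_layout=layout,
    )
    return seq, truth


def make_srna(
    spec: SrnaArchitectureSpec,
    rng_seed: int | np.random.Generator,
    seq_id: str = "synthetic_srna",
) -> tuple[RnaSequence, DotBracketStructure, GroundTruth]:
    """Generate an sRNA with the shared modular architecture and its
    dot-bracket ground truth (planted stems paired, motif unpaired).

    Stems and spacers avoid A and long U-runs so the planted motif and
    poly(U) tail remain the only instances of their features.
    """
    rng = _rng(rng_seed)
    truth = GroundTruth(seq_id=seq_id)

    def loop_seq(length: int, seed: Optional[str]) -> tuple[str, Optional[tuple[int, int]]]:
        body = "".join(rng.choice(list("CGU"), size=length))
        if seed is None:
            return body, None
        pos = int(rng.integers(0, length - len(seed) + 1))
        return body[:pos] + seed + body[pos + len(seed):], (pos, pos + len(seed) - 1)

    def stem_seq(length: int) -> str:
        return "".join(rng.choice(list("CG"), size=length))

    parts: list[str] = []
    db: list[str] = []
    cursor = 0

    def add(seq_part: str, struct_part: str) -> tuple[int, int]:
        nonlocal cursor
        parts.append(seq_part)
        db.append(struct_part)
        iv = (cursor + 1, cursor + len(seq_part))
        cursor += len(seq_part)
        return iv

    # 5' stem-loop
    stem5 = stem_seq(spec.stem5_len)
    loop5, seed5_rel = loop_seq(spec.loop5_len, spec.seed_5p)
    h5_start = cursor + 1
    add(stem5, "(" * spec.stem5_len)
    loop5_iv = add(loop5, "." * spec.loop5_len)
    add("".join(_COMP[c] for c in reversed(stem5)), ")" * spec.stem5_len)
    truth.hairpin_intervals.append(Interval(seq_id, h5_start, cursor))
    if seed5_rel:
        truth.seed_intervals.append(
            Interval(seq_id, loop5_iv[0] + seed5_rel[0], loop5_iv[0] + seed5_rel[1])
        )

    # motif; resample so the final triplet cannot seed a frame-shifted
    # ARN triplet into the 3' flank (keeps the scanned region exactly the
    # planted interval: an R=A,N∈{A,G} or N=A ending would let a match
    # extend 1-2 nt into the spacer via a gap element)
    for _ in range(100):
        motif_seq, layout = _motif_sequence(spec.motif, rng)
        r_base, n_base = motif_seq[-2], motif_seq[-1]
        if not (r_base == "A" and n_base in "AG") and n_base != "A":
            break
    motif_iv = add(motif_seq, "." * len(motif_seq))
    truth.motif_intervals.append(Interval(seq_id, *motif_iv))
    truth.motif_layout = layout

    # the motif-to-tail stretch: the 3' stem-loop lies INSIDE it, so the
    # planted spacing is the distance the scanner's poly(U) measurement
    # recovers (motif end -> first tail U, exclusive)
    spacer = (
        spec.spacer_to_poly_u
        if spec.spacer_to_poly_u is not None
        else int(rng.integers(20, 41))
    )
    block = 2 * spec.stem3_len + spec.loop3_len
    if spacer < block:
        raise ValueError(
            f"spacer_to_poly_u ({spacer}) shorter than the 3' stem-loop "
            f"({block} nt) it must contain"
        )
    gap_a = (spacer - block + 1) // 2
    gap_b = spacer - block - gap_a
    # the residue following the motif is fixed to C so no ARN triplet can
    # straddle the motif/spacer boundary
    gap_a_seq = "C" + "".join(rng.choice(list("CG"), size=gap_a - 1)) if gap_a else ""
    add(gap_a_seq, "." * gap_a)
    stem3 = stem_seq(spec.stem3_len)
    if gap_a == 0:
        stem3 = "C" + stem3[1:]
    loop3, seed3_rel = loop_seq(spec.loop3_len, spec.seed_3p)
    h3_start = cursor + 1
    add(stem3, "(" * spec.stem3_len)
    loop3_iv = add(loop3, "." * spec.loop3_len)
    add("".join(_COMP[c] for c in reversed(stem3)), ")" * spec.stem3_len)
    truth.hairpin_intervals.append(Interval(seq_id, h3_start, cursor))
    if seed3_rel:
        truth.seed_intervals.append(
            Interval(seq_id, loop3_iv[0] + seed3_rel[0], loop3_iv[0] + seed3_rel[1])
        )
    add("".join(rng.choice(list("CG"), size=gap_b)), "." * gap_b)
    add("U" * spec.poly_u_len, "." * spec.poly_u_len)
    truth.poly_u_spacing = spacer

    seq = RnaSequence(id=seq_id, residues="".join(parts))
    structure = DotBracketStructure(seq_id=seq_id, brackets="".join(db))
    return seq, structure, truth


# ---------------------------------------------------------------------------
# null models
# ---------------------------------------------------------------------------

def shuffle_null(
    seq: RnaSequence, mode: str, rng_seed: int | np.random.Generator
) -> RnaSequence:
    """Composition-preserving shuffle for background hit-rate estimation.

    ``mononucleotide`` permutes residues uniformly; ``dinucleotide``
    preserves all 16 dinucleotide counts (and the first and last
    residue) via a random Eulerian trail through the dinucleotide
    multigraph (Altschul-Erickson shuffle).
    """
    rng = _rng(rng_seed)
    res = seq.residues
    if mode == "mononucleotide":
        arr = np.array(list(res))
        rng.shuffle(arr)
        return RnaSequence(id=seq.id + "_shuf", residues="".join(arr))
    if mode != "dinucleotide":
        raise ValueError(f"unknown shuffle mode {mode!r}")
    if len(res) < 2:
        raise ValueError("dinucleotide shuffle needs length >= 2")

    # multigraph: edge res[i] -> res[i+1]
    edges: dict[str, list[str]] = {}
    for a, b in zip(res, res[1:]):
        edges.setdefault(a, []).append(b)
    first, last = res[0], res[-1]

    # randomized Eulerian trail: shuffle each adjacency list, walk from the
    # first residue consuming edges in order, retry if the walk stalls
    # before using every edge (rejection keeps the trail uniform enough
    # for a null model and terminates fast on 4-letter alphabets)
    for _ in range(10000):
        trial = {a: [bs[i] for i in rng.permutation(len(bs))] for a, bs in edges.items()}
        consumed = {a: 0 for a in trial}
        cur = first
        seq_out = [first]
        while True:
            succ = trial.get(cur, [])
            i = consumed.get(cur, 0)
            if i >= len(succ):
                break
            consumed[cur] = i + 1
            cur = succ[i]
            seq_out.append(cur)
        if len(seq_out) == len(res):
            return RnaSequence(id=seq.id + "_shuf", residues="".join(seq_out))
    raise RuntimeError("dinucleotide shuffle failed to find an Eulerian trail")


def make_alignment(
    reference: RnaSequence,
    n_rows: int,
    mutation_rate: float,
    rng_seed: int | np.random.Generator,
    protect_motif: bool = False,
    protected_positions: Optional[set[int]] = None,
    protected_factor: float = 0.1,
    gap_rate: float = 0.0,
    reference_id: Optional[str] = None,
) -> Alignment:
    """Simulate a homolog alignment by per-column i.i.d. substitution.

    Row 0 is the unmutated reference.  With ``protect_motif``, columns in
    ``protected_positions`` (1-based reference positions, e.g. the A/R
    sites of a planted motif) mutate at ``mutation_rate *
    protected_factor``, emulating purifying selection on functional
    positions.  ``gap_rate`` deletes residues ('-') in non-reference
    rows; the reference stays ungapped so reference-coordinate mapping
    is total.
    """
    if not (0 <= mutation_rate <= 1 and 0 <= gap_rate <= 1):
        raise ValueError("rates must be within [0, 1]")
    rng = _rng(rng_seed)
    protected = protected_positions or set()
    ref = reference.residues
    rows = [(reference_id or reference.id, ref)]
    for r in range(1, n_rows):
        chars = []
        for pos, base in enumerate(ref, start=1):
            rate = mutation_rate
            if protect_motif and pos in protected:
                rate *= protected_factor
            if rng.random() < gap_rate:
                chars.append("-")
            elif base in _BASES and rng.random() < rate:
                chars.append(str(rng.choice([b for b in _BASES if b != base])))
            else:
                chars.append(base)
        rows.append((f"homolog_{r}", "".join(chars)))
    return Alignment(rows=tuple(rows))
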