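"""Sequence, alignment and structure I/O plus the coordinate conventions
shared by every other module.

Conventions
-----------
* The working alphabet is ``{A, C, G, U, 0}`` where ``0`` is an abasic
  residue (intact backbone, no base).  DNA input is silently normalized
  to RNA (``T``/``t`` -> ``U``) and case is folded to upper.
* All coordinates are 1-based and inclusive.  A sequence may carry an
  ``offset`` so that matches on a sub-fragment are reported in the
  numbering of the parent molecule (e.g. an oligonucleotide spanning
  nucleotides 57-86 of a full-length sRNA).
* mRNA 5' windows use signed coordinates relative to the start codon
  (+1 = first nucleotide of the start codon).  Position 0 does not
  exist: -1 is directly adjacent to +1.  ``to_native``/``from_native``
  implement this convention for negative offsets.
* BED export alone is 0-based half-open; TSV reports stay 1-based.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGU0")

__all__ = [
    "ALPHABET",
    "RnaSequence",
    "Interval",
    "Alignment",
    "DotBracketStructure",
    "AlphabetError",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "read_dotbracket",
    "write_dotbracket",
    "to_native",
    "from_native",
    "native_to_linear",
    "linear_to_native",
    "write_regions",
]


class AlphabetError(ValueError):
    """A residue outside {A, C, G, U, 0} after normalization."""


class FastaParseError(ValueError):
    """Malformed FASTA input."""


def _normalize(raw: str, seq_id: str = "?") -> str:
    out = raw.upper().replace("T", "U")
    for i, ch in enumerate(out, start=1):
        if ch not in ALPHABET:
            raise AlphabetError(
                f"illegal character {ch!r} at position {i} of sequence {seq_id!r}"
            )
    return out


@dataclass(frozen=True)
class RnaSequence:
    """An identified RNA sequence with a native-coordinate offset.

    ``offset`` is the 1-based coordinate of the first residue in the
    numbering of the parent molecule; negative offsets follow the
    no-position-zero convention of mRNA 5' windows.
    """

    id: str
    residues: str
    offset: int = 1

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        object.__setattr__(self, "residues", _normalize(self.residues, self.id))
        if self.offset < -10000:
            raise ValueError(f"offset {self.offset} below supported range")
        if self.offset == 0:
            raise ValueError("offset 0 is not a valid coordinate (no position 0)")

    def __len__(self) -> int:
        return len(self.residues)

    def subseq(self, start: int, end: int) -> str:
        """Residues at local 1-based inclusive positions [start, end]."""
        if not (1 <= start <= end <= len(self)):
            raise IndexError(f"[{start},{end}] out of range for {self.id!r}")
        return self.residues[start - 1 : end]


@dataclass(frozen=True, order=True)
class Interval:
    """A 1-based inclusive interval on a named sequence."""

    seq_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Interval") -> bool:
        return self.start <= other.end and other.start <= self.end

    def contains(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end


@dataclass(frozen=True)
class Alignment:
    """A gapped multiple sequence alignment; gap character is '-'."""

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        ncol = len(self.rows[0][1])
        for rid, seq in self.rows:
            if len(seq) != ncol:
                raise ValueError(f"row {rid!r} length differs from first row")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    def row(self, row_id: str) -> str:
        for rid, seq in self.rows:
            if rid == row_id:
                return seq
        raise KeyError(f"no alignment row {row_id!r}")


@dataclass(frozen=True)
class DotBracketStructure:
    """Secondary structure in Vienna dot-bracket notation."""

    seq_id: str
    brackets: str

    def __post_init__(self) -> None:
        depth = 0
        for i, ch in enumerate(self.brackets, start=1):
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    raise ValueError(f"unbalanced ')' at position {i}")
            elif ch != ".":
                raise ValueError(f"illegal structure character {ch!r} at position {i}")
        if depth != 0:
            raise ValueError(f"{depth} unclosed '(' in structure {self.seq_id!r}")

    def __len__(self) -> int:
        return len(self.brackets)

    def pair_table(self) -> dict[int, int]:
        """1-based position -> paired position, both directions."""
        stack: list[int] = []
        pairs: dict[int, int] = {}
        for i, ch in enumerate(self.brackets, start=1):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                j = stack.pop()
                pairs[i] = j
                pairs[j] = i
        return pairs


# ---------------------------------------------------------------------------
# coordinate arithmetic
# ---------------------------------------------------------------------------

def to_native(seq: RnaSequence, local_pos: int) -> int:
    """Map a local 1-based position onto the parent molecule's numbering.

    For negative offsets the result skips the non-existent position 0.
    """
    if not (1 <= local_pos <= len(seq)):
        raise IndexError(
            f"local position {local_pos} out of range 1..{len(seq)} for {seq.id!r}"
        )
    native = seq.offset + local_pos - 1
    if seq.offset < 0 and native >= 0:
        native += 1
    return native


def from_native(seq: RnaSequence, native_pos: int) -> int:
    """Inverse of :func:`to_native`."""
    if native_pos == 0:
        raise ValueError("position 0 does not exist in this numbering")
    local = native_pos - seq.offset + 1
    if seq.offset < 0 and native_pos > 0:
        local -= 1
    if not (1 <= local <= len(seq)):
        raise IndexError(f"native position {native_pos} outside {seq.id!r}")
    return local


def native_to_linear(pos: int) -> int:
    """Collapse signed no-zero numbering onto the integers (for distances)."""
    if pos == 0:
        raise ValueError("position 0 does not exist")
    return pos if pos > 0 else pos + 1


def linear_to_native(lin: int) -> int:
    return lin if lin >= 1 else lin - 1


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _parse_offset(description: str) -> int:
    for token in description.split():
        if token.startswith("offset="):
            try:
                return int(token[len("offset="):])
            except ValueError as exc:
                raise FastaParseError(f"bad offset token {token!r}") from exc
    return 1


def read_fasta(path: str | Path) -> list[RnaSequence]:
    """Read FASTA into normalized :class:`RnaSequence` records.

    The header may carry an ``offset=<int>`` token giving the native
    coordinate of the first residue (default 1).
    """
    path = Path(path)
    with path.open() as handle:
        first = handle.readline()
        if first and not first.startswith(">"):
            raise FastaParseError(f"{path}: line 1 does not start with '>'")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        offset = _parse_offset(rec.description)
        out.append(RnaSequence(id=rec.id, residues=str(rec.seq), offset=offset))
    return out


def write_fasta(seqs: Iterable[RnaSequence], path: str | Path) -> None:
    records = []
    for s in seqs:
        desc = f"offset={s.offset}" if s.offset != 1 else ""
        records.append(SeqRecord(Seq(s.residues), id=s.id, description=desc))
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# alignments and structures
# ---------------------------------------------------------------------------

def read_alignment(path: str | Path, fmt: str = "fasta") -> Alignment:
    """Read an aligned FASTA or Clustal file into an :class:`Alignment`."""
    if fmt not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format {fmt!r}")
    aln = AlignIO.read(str(path), fmt)
    rows = tuple(
        (rec.id, str(rec.seq).upper().replace("T", "U")) for rec in aln
    )
    return Alignment(rows=rows)


def read_dotbracket(path: str | Path) -> list[DotBracketStructure]:
    """Read Vienna-style structures: '>id' header, sequence line optional,
    one dot-bracket line per record."""
    structures = []
    seq_id = None
    with Path(path).open() as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                seq_id = line[1:].split()[0]
            elif set(line) <= {"(", ")", "."}:
                structures.append(
                    DotBracketStructure(seq_id=seq_id or "?", brackets=line)
                )
            # bare sequence lines between header and structure are skipped
    if not structures:
        raise ValueError(f"{path}: no dot-bracket lines found")
    return structures


def write_dotbracket(
    structures: Iterable[DotBracketStructure], path: str | Path
) -> None:
    with Path(path).open("w") as handle:
        for s in structures:
            handle.write(f">{s.seq_id}\n{s.brackets}\n")


# ---------------------------------------------------------------------------
# region reports
# ---------------------------------------------------------------------------

_TSV_HEADER = "seq_id\tstart\tend\tn_arn\tn_nonfunctional\tn_gaps"


def write_regions(regions: Sequence, path: str | Path, format: str = "tsv") -> None:
    """Write motif regions as TSV (1-based inclusive) or BED (0-based
    half-open).

    Accepts any objects exposing ``interval`` plus ``max_arn`` /
    ``n_nonfunctional`` / ``n_gaps`` attributes (motif regions), or bare
    :class:`Interval` objects (counts written as 0).
    """
    if format not in ("tsv", "bed"):
        raise ValueError(f"unsupported region format {format!r}")
    rows = []
    for region in regions:
        iv = getattr(region, "interval", region)
        rows.append(
            (
                iv.seq_id,
                iv.start,
                iv.end,
                getattr(region, "max_arn", 0),
                getattr(region, "n_nonfunctional", 0),
                getattr(region, "n_gaps", 0),
            )
        )
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    buf = io.StringIO()
    if format == "tsv":
        buf.write(_TSV_HEADER + "\n")
        for r in rows:
            buf.write("\t".join(map(str, r)) + "\n")
    else:
        for r in rows:
            buf.write(f"{r[0]}\t{r[1] - 1}\t{r[2]}\n")
    Path(path).write_text(buf.getvalue())
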