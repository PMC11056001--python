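"""Circular-sequence algorithms: reverse complement, wrap-around Hamming
matching, anchor-hit enumeration on both strands, and rotation.

A linearized circular molecule is an arbitrary rotation of the underlying
circle, so all matching here reads positions modulo the sequence length:
an anchor occurrence that spans the linearization origin is a first-class
hit. Coordinates are 0-based throughout the library; the CLI converts to
1-based only when printing diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

FORWARD: Literal["forward"] = "forward"
REVERSE: Literal["reverse"] = "reverse"
Strand = Literal["forward", "reverse"]

__all__ = [
    "FORWARD",
    "REVERSE",
    "SequenceRecord",
    "AnchorQuery",
    "AnchorHit",
    "RotationOutcome",
    "RotateError",
    "EmptySequenceError",
    "AnchorTooLongError",
    "AnchorNotFoundError",
    "AmbiguousAnchorError",
    "reverse_complement",
    "circular_window_mismatches",
    "find_anchor_hits",
    "rotate_by_offset",
    "rotate_to_anchor",
]


# --------------------------------------------------------------------------
# Errors

class RotateError(Exception):
    """Base class for per-record rotation failures; carries the record name."""

    def __init__(self, record_name: str, message: str):
        self.record_name = record_name
        super().__init__(message)


class EmptySequenceError(RotateError):
    """A zero-length circle has no rotation."""

    def __init__(self, record_name: str):
        super().__init__(record_name, f"record {record_name!r}: empty sequence")


class AnchorTooLongError(RotateError):
    """The anchor cannot be longer than the sequence it is searched in."""

    def __init__(self, record_name: str, anchor_length: int, seq_length: int):
        super().__init__(
            record_name,
            f"record {record_name!r}: anchor length {anchor_length} exceeds "
            f"sequence length {seq_length}",
        )


class AnchorNotFoundError(RotateError):
    """No anchor occurrence within the mismatch budget on either strand."""

    def __init__(self, record_name: str):
        super().__init__(record_name, f"record {record_name!r}: anchor not found")


class AmbiguousAnchorError(RotateError):
    """More than one (position, strand) pair within the mismatch budget.

    Carries the full hit list so callers can report every candidate location.
    """

    def __init__(self, record_name: str, hits: list["AnchorHit"]):
        self.hits = list(hits)
        super().__init__(
            record_name,
            f"record {record_name!r}: anchor is not unique "
            f"({len(self.hits)} hits)",
        )


# --------------------------------------------------------------------------
# Domain types

@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA entry, treated as a circular molecule.

    ``description`` is the full header line after '>'; ``name`` is its first
    whitespace-delimited token. Residues are kept verbatim (any case, N,
    IUPAC codes and '-' gaps all survive round-trips).
    """

    description: str
    residues: str
    name: str = field(init=False)

    def __post_init__(self) -> None:
        if "\n" in self.residues or ">" in self.residues:
            raise ValueError("residues may not contain newline or '>' characters")
        token = self.description.split()
        object.__setattr__(self, "name", token[0] if token else "")

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AnchorQuery:
    """An anchor string plus mismatch budget: the search specification.

    The budget must be strictly smaller than the anchor length; a budget
    that allows every position to mismatch would make every offset a hit.
    """

    anchor: str
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        if len(self.anchor) < 1:
            raise ValueError("anchor must be non-empty")
        if not self.anchor.isalpha():
            raise ValueError("anchor must contain only alphabetic characters")
        if self.max_mismatches < 0:
            raise ValueError("mismatch budget must be non-negative")
        if self.max_mismatches >= len(self.anchor):
            raise ValueError(
                f"mismatch budget {self.max_mismatches} must be smaller than "
                f"the anchor length {len(self.anchor)}"
            )


@dataclass(frozen=True)
class AnchorHit:
    """One candidate match before any rotation is applied.

    ``start`` is a 0-based window start on the forward sequence for forward
    hits, and on the reverse-complemented sequence for reverse hits — so the
    reported number is directly the rotation offset that would be applied.
    """

    start: int
    strand: Strand
    mismatches: int


@dataclass(frozen=True)
class RotationOutcome:
    """A rotated record plus provenance.

    ``applied_offset`` is the normalized shift in [0, L); ``flipped`` records
    whether the output is the reverse complement of the input; ``hit`` is the
    anchor hit used (None in offset mode).
    """

    record: SequenceRecord
    applied_offset: int
    flipped: bool
    hit: Optional[AnchorHit] = None


# --------------------------------------------------------------------------
# Reverse complement

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "K": "M", "M": "K",
    "S": "S", "W": "W", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}


def _build_complement_table() -> dict[int, str]:
    table: dict[int, str] = {}
    for code in range(256):
        ch = chr(code)
        upper = ch.upper()
        if upper in _COMPLEMENT:
            comp = _COMPLEMENT[upper]
            table[code] = comp.lower() if ch.islower() else comp
        elif ch == "-":
            table[code] = "-"
        elif ch.islower():
            table[code] = "n"
        else:
            table[code] = "N"
    return table


_COMPLEMENT_TABLE = str.maketrans(_build_complement_table())


def reverse_complement(seq: str) -> str:
    """Return the reverse complement, preserving case.

    IUPAC ambiguity codes map to their complements (R<->Y, K<->M, S, W,
    B<->V, D<->H), N stays N and '-' stays '-'; any other character becomes
    N (n if the input was lowercase).
    """
    return seq.translate(_COMPLEMENT_TABLE)[::-1]


# --------------------------------------------------------------------------
# Circular matching

def circular_window_mismatches(seq: str, pos: int, pattern: str) -> int:
    """Hamming distance between ``pattern`` and the circular window of
    ``len(pattern)`` residues starting at ``pos`` on ``seq``.

    Indices are read modulo ``len(seq)``, so the window may span the
    linearization origin. Comparison is case-insensitive and literal: N
    matches only N, a gap matches only a gap; no IUPAC wildcard expansion.
    """
    length = len(seq)
    if not 0 <= pos < length:
        raise ValueError(f"position {pos} out of range for sequence of length {length}")
    if len(pattern) > length:
        raise ValueError(
            f"pattern length {len(pattern)} exceeds sequence length {length}"
        )
    s = seq.upper()
    p = pattern.upper()
    return sum(1 for j, pc in enumerate(p) if s[(pos + j) % length] != pc)


def _scan_strand(seq_upper: bytes, pattern_upper: bytes, budget: int) -> list[tuple[int, int]]:
    """All (start, mismatches) with mismatches <= budget, circular, 0-based.

    Vectorized modular-index scan: for each pattern column j, compare the
    sequence cyclically shifted by j against pattern[j] and accumulate
    per-start mismatch counts.
    """
    arr = np.frombuffer(seq_upper, dtype=np.uint8)
    mism = np.zeros(arr.size, dtype=np.int64)
    for j, pat_byte in enumerate(pattern_upper):
        mism += np.roll(arr, -j) != pat_byte
    starts = np.nonzero(mism <= budget)[0]
    return [(int(p), int(mism[p])) for p in starts]


def find_anchor_hits(
    record: SequenceRecord,
    query: AnchorQuery,
    search_reverse: bool = True,
) -> list[AnchorHit]:
    """Enumerate every anchor occurrence within the mismatch budget.

    Returns all forward-strand hits (window starts on the forward sequence),
    then, if ``search_reverse``, all hits on the reverse-complemented
    sequence, each group in ascending start order. Matching is circular, so
    occurrences spanning the origin are found; only starts in [0, L) are
    reported, so no duplicates arise.
    """
    length = record.length
    w = len(query.anchor)
    if length < 1 or w > length:
        raise AnchorTooLongError(record.name, w, length)

    pattern = query.anchor.upper().encode("latin-1")
    budget = query.max_mismatches

    hits = [
        AnchorHit(start, FORWARD, mm)
        for start, mm in _scan_strand(
            record.residues.upper().encode("latin-1"), pattern, budget
        )
    ]
    if search_reverse:
        rc = reverse_complement(record.residues)
        hits.extend(
            AnchorHit(start, REVERSE, mm)
            for start, mm in _scan_strand(rc.upper().encode("latin-1"), pattern, budget)
        )
    return hits


# --------------------------------------------------------------------------
# Rotation

def rotate_by_offset(record: SequenceRecord, x: int) -> RotationOutcome:
    """Rotate so that the input's position ``x mod L`` becomes position 0.

    A 0-based shift: x=0 is the identity; negative and >=L offsets are
    normalized modulo L. Works on any alphabet, including alignment gaps,
    so already-aligned sequences can be offset too. The header is preserved
    verbatim.
    """
    length = record.length
    if length == 0:
        raise EmptySequenceError(record.name)
    k = x % length
    rotated = record.residues[k:] + record.residues[:k]
    return RotationOutcome(
        record=SequenceRecord(record.description, rotated),
        applied_offset=k,
        flipped=False,
    )


def rotate_to_anchor(
    record: SequenceRecord,
    query: AnchorQuery,
    search_reverse: bool = True,
) -> RotationOutcome:
    """Rotate so the unique anchor occurrence starts at position 0.

    Uniqueness is strict: exactly one (position, strand) pair within the
    budget across both searched strands, not "one best hit" — two hits with
    different mismatch counts are still ambiguous. For a reverse-strand hit
    the whole record is reverse-complemented first, so every successful
    output presents the anchor on the forward strand starting at residue 1.

    Raises AnchorNotFoundError on zero hits and AmbiguousAnchorError
    (carrying the full hit list) on two or more.
    """
    hits = find_anchor_hits(record, query, search_reverse=search_reverse)
    if not hits:
        raise AnchorNotFoundError(record.name)
    if len(hits) > 1:
        raise AmbiguousAnchorError(record.name, hits)
    (hit,) = hits
    if hit.strand == FORWARD:
        base = record
        flipped = False
    else:
        base = SequenceRecord(record.description, reverse_complement(record.residues))
        flipped = True
    rotated = rotate_by_offset(base, hit.start)
    return RotationOutcome(
        record=rotated.record,
        applied_offset=hit.start,
        flipped=flipped,
        hit=hit,
    )
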