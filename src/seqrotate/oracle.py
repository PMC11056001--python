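"""Brute-force reference matcher, used only for equivalence testing.

Deliberately implemented with a different mechanism than the production
matcher: the sequence is materialized as a doubled string (so circular
windows become ordinary slices) and every window is compared character by
character with a full count and no early exit. It shares no matching code
with the production path, so the two implementations can fail
independently.
"""

from __future__ import annotations

from .core import FORWARD, REVERSE, AnchorHit, AnchorQuery, SequenceRecord

__all__ = ["brute_force_hits"]

# Independent complement table (full IUPAC set), written separately from the
# production one on purpose.
_COMP = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "M": "K", "R": "Y", "W": "W", "S": "S", "Y": "R", "K": "M",
    "V": "B", "H": "D", "D": "H", "B": "V", "N": "N", "-": "-",
}


def _naive_revcomp(seq: str) -> str:
    out = []
    for ch in reversed(seq):
        comp = _COMP.get(ch.upper(), "N")
        out.append(comp.lower() if ch.islower() else comp)
    return "".join(out)


def brute_force_hits(
    record: SequenceRecord,
    query: AnchorQuery,
    search_reverse: bool = True,
) -> list[AnchorHit]:
    """Every circular anchor occurrence within the budget, by exhaustion."""
    length = record.length
    w = len(query.anchor)
    if length < 1 or w > length:
        raise ValueError("anchor longer than sequence")
    pattern = query.anchor.upper()
    budget = query.max_mismatches

    def scan(seq: str, strand: str) -> list[AnchorHit]:
        doubled = (seq + seq).upper()
        found = []
        for start in range(length):
            window = doubled[start : start + w]
            distance = sum(a != b for a, b in zip(window, pattern))
            if distance <= budget:
                found.append(AnchorHit(start, strand, distance))
        return found

    hits = scan(record.residues, FORWARD)
    if search_reverse:
        hits.extend(scan(_naive_revcomp(record.residues), REVERSE))
    return hits
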