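"""Unit and property tests for the circular-sequence algorithms."""

import random

import pytest
from hypothesis import given, strategies as st

from seqrotate import (
    AmbiguousAnchorError,
    AnchorHit,
    AnchorNotFoundError,
    AnchorQuery,
    AnchorTooLongError,
    EmptySequenceError,
    SequenceRecord,
    circular_window_mismatches,
    find_anchor_hits,
    reverse_complement,
    rotate_by_offset,
    rotate_to_anchor,
)

from conftest import MITO_ANCHOR, BARCODE_ANCHOR, random_dna

FULL_ALPHABET = "ACGTacgtNnRYKMSWBVDHrykmswbvdh-"
dna_text = st.text(alphabet=FULL_ALPHABET, min_size=0, max_size=80)


# --------------------------------------------------------------------------
# reverse_complement

@pytest.mark.parametrize(
    "seq,expected",
    [
        ("", ""),
        ("ACGT", "ACGT"),  # its own reverse complement
        ("AAACg", "cGTTT"),
        ("N-n", "n-N"),
        ("RYKMSWBVDH", "DHBVWSKMRY"),
        ("Q?z", "nNN"),  # unknowns collapse to N, case kept
    ],
)
def test_reverse_complement_examples(seq, expected):
    assert reverse_complement(seq) == expected


@given(dna_text)
def test_reverse_complement_is_involution(seq):
    assert reverse_complement(reverse_complement(seq)) == seq


@given(dna_text)
def test_reverse_complement_preserves_length_and_case_pattern(seq):
    rc = reverse_complement(seq)
    assert len(rc) == len(seq)
    assert [c.islower() for c in rc] == [c.islower() for c in reversed(seq)]


# --------------------------------------------------------------------------
# circular_window_mismatches

@pytest.mark.parametrize(
    "seq,pos,pattern,expected",
    [
        ("ACGTACGT", 0, "ACGT", 0),
        ("ACGTAC", 4, "ACAC", 0),  # window wraps past the origin
        ("AAAAAA", 3, "AATA", 1),
        ("acgt", 0, "ACGT", 0),  # case-insensitive
        ("ANGT", 0, "ANGT", 0),  # N matches only N ...
        ("ANGT", 0, "AAGT", 1),  # ... not as a wildcard
        ("A-GT", 0, "AAGT", 1),  # gap matches only gap
    ],
)
def test_window_mismatch_examples(seq, pos, pattern, expected):
    assert circular_window_mismatches(seq, pos, pattern) == expected


def test_window_mismatch_errors():
    with pytest.raises(ValueError):
        circular_window_mismatches("ACGT", 4, "A")
    with pytest.raises(ValueError):
        circular_window_mismatches("ACGT", -1, "A")
    with pytest.raises(ValueError):
        circular_window_mismatches("ACGT", 0, "ACGTA")


# --------------------------------------------------------------------------
# find_anchor_hits

def test_planted_forward_anchor_found_exactly_once():
    record = SequenceRecord("mito", MITO_ANCHOR + "A" * 79)
    hits = find_anchor_hits(record, AnchorQuery(MITO_ANCHOR, 0))
    assert hits == [AnchorHit(0, "forward", 0)]


def test_planted_reverse_anchor_found_on_reverse_strand():
    record = SequenceRecord(
        "chloro", "C" * 50 + reverse_complement(BARCODE_ANCHOR) + "C" * 30
    )
    hits = find_anchor_hits(record, AnchorQuery(BARCODE_ANCHOR, 1))
    assert len(hits) == 1
    assert hits[0].strand == "reverse"
    assert hits[0].mismatches == 0


def test_origin_spanning_hit_is_found():
    # anchor split across the linearization origin: tail | ... | head
    anchor = "TACGATTGCA"
    record = SequenceRecord("wrap", anchor[6:] + "G" * 40 + anchor[:6])
    hits = find_anchor_hits(record, AnchorQuery(anchor, 0), search_reverse=False)
    assert [h.start for h in hits] == [44]


def test_no_reverse_search_when_disabled():
    record = SequenceRecord("r", reverse_complement(MITO_ANCHOR) + "C" * 50)
    query = AnchorQuery(MITO_ANCHOR, 0)
    assert find_anchor_hits(record, query, search_reverse=False) == []
    assert len(find_anchor_hits(record, query, search_reverse=True)) == 1


def test_anchor_longer_than_sequence_raises_named_error():
    record = SequenceRecord("short", "ACG")
    with pytest.raises(AnchorTooLongError) as excinfo:
        find_anchor_hits(record, AnchorQuery("ACGTT", 0))
    assert excinfo.value.record_name == "short"


def test_hit_ordering_forward_then_reverse_ascending():
    # "ACGT" is its own reverse complement -> symmetric hits on both strands
    record = SequenceRecord("p", "ACGTACGT")
    hits = find_anchor_hits(record, AnchorQuery("GTAC", 0))
    assert hits == [
        AnchorHit(2, "forward", 0),
        AnchorHit(6, "forward", 0),
        AnchorHit(2, "reverse", 0),
        AnchorHit(6, "reverse", 0),
    ]


# --------------------------------------------------------------------------
# AnchorQuery validation

@pytest.mark.parametrize(
    "anchor,m",
    [("", 0), ("ACGT", 4), ("ACGT", -1), ("AC-T", 0), ("ACG T", 0)],
)
def test_invalid_queries_rejected_at_construction(anchor, m):
    with pytest.raises(ValueError):
        AnchorQuery(anchor, m)


# --------------------------------------------------------------------------
# rotate_by_offset

@pytest.mark.parametrize(
    "residues,x,expected",
    [
        ("ABCDEF", 2, "CDEFAB"),
        ("ABCDEF", 0, "ABCDEF"),
        ("ABCDEF", 6, "ABCDEF"),
        ("ABCDEF", -1, "FABCDE"),
        ("AC-GT", 2, "-GTAC"),  # gapped (aligned) input rotates too
    ],
)
def test_rotate_by_offset_examples(residues, x, expected):
    outcome = rotate_by_offset(SequenceRecord("r desc", residues), x)
    assert outcome.record.residues == expected
    assert outcome.record.description == "r desc"
    assert outcome.applied_offset == x % len(residues)
    assert outcome.flipped is False


def test_rotate_empty_sequence_raises():
    with pytest.raises(EmptySequenceError):
        rotate_by_offset(SequenceRecord("empty", ""), 0)


@given(
    st.text(alphabet=FULL_ALPHABET, min_size=1, max_size=60),
    st.integers(-200, 200),
    st.integers(-200, 200),
)
def test_rotation_group_laws(residues, a, b):
    record = SequenceRecord("g", residues)
    length = len(residues)
    once = rotate_by_offset(record, a)
    # inverse: rotating back by L - a restores the input
    back = rotate_by_offset(once.record, length - (a % length))
    assert back.record.residues == residues
    # composition: successive rotations add
    twice = rotate_by_offset(once.record, b)
    direct = rotate_by_offset(record, a + b)
    assert twice.record.residues == direct.record.residues


@given(st.text(alphabet=FULL_ALPHABET, min_size=1, max_size=60), st.integers(-50, 50))
def test_rotation_conserves_residue_multiset(residues, x):
    outcome = rotate_by_offset(SequenceRecord("g", residues), x)
    assert sorted(outcome.record.residues) == sorted(residues)
    assert outcome.record.length == len(residues)


# --------------------------------------------------------------------------
# rotate_to_anchor

def test_recovers_planted_rotation():
    rng = random.Random(99)
    unrotated = MITO_ANCHOR + random_dna(rng, 979)
    # guard against accidental extra hits in the random tail
    probe = SequenceRecord("g", unrotated)
    assert len(find_anchor_hits(probe, AnchorQuery(MITO_ANCHOR, 0))) == 1
    rotated = unrotated[-500:] + unrotated[:-500]
    outcome = rotate_to_anchor(SequenceRecord("g", rotated), AnchorQuery(MITO_ANCHOR, 0))
    assert outcome.record.residues.startswith(MITO_ANCHOR)
    assert outcome.applied_offset == 500
    assert outcome.flipped is False


def test_two_planted_copies_are_ambiguous():
    record = SequenceRecord("dup", "TACGA" * 2 + "C" * 90)
    with pytest.raises(AmbiguousAnchorError) as excinfo:
        rotate_to_anchor(record, AnchorQuery("TACGA", 0))
    assert excinfo.value.record_name == "dup"
    assert excinfo.value.hits == [
        AnchorHit(0, "forward", 0),
        AnchorHit(5, "forward", 0),
    ]


def test_absent_anchor_raises_notfound_with_record_name():
    record = SequenceRecord("allg", "G" * 100)
    with pytest.raises(AnchorNotFoundError) as excinfo:
        rotate_to_anchor(record, AnchorQuery("TACGA", 0))
    assert excinfo.value.record_name == "allg"


def test_unequal_mismatch_counts_are_still_ambiguous():
    # one exact copy + one copy at distance 1: uniqueness is strict,
    # not best-hit selection
    record = SequenceRecord("d", "TACGA" + "TACTA" + "C" * 90)
    with pytest.raises(AmbiguousAnchorError) as excinfo:
        rotate_to_anchor(record, AnchorQuery("TACGA", 1))
    assert sorted(h.mismatches for h in excinfo.value.hits) == [0, 1]


def test_reverse_hit_flips_record_and_presents_anchor_forward():
    rng = random.Random(7)
    forward_version = BARCODE_ANCHOR + random_dna(rng, 200)
    assert (
        len(find_anchor_hits(SequenceRecord("f", forward_version), AnchorQuery(BARCODE_ANCHOR, 0)))
        == 1
    )
    record = SequenceRecord("r", reverse_complement(forward_version))
    outcome = rotate_to_anchor(record, AnchorQuery(BARCODE_ANCHOR, 0))
    assert outcome.flipped is True
    assert outcome.record.residues.startswith(BARCODE_ANCHOR)


def test_strand_symmetry():
    # planting on the forward strand of g and on the reverse strand of
    # revcomp(g) must give identical rotated output
    rng = random.Random(11)
    genome = MITO_ANCHOR + random_dna(rng, 400)
    query = AnchorQuery(MITO_ANCHOR, 0)
    fwd_out = rotate_to_anchor(SequenceRecord("a", genome), query)
    rev_out = rotate_to_anchor(
        SequenceRecord("a", reverse_complement(genome)), query
    )
    assert fwd_out.record.residues == rev_out.record.residues


def test_output_prefix_within_budget():
    rng = random.Random(5)
    for trial in range(20):
        genome = list(MITO_ANCHOR + random_dna(rng, 300))
        # mutate up to 4 anchor positions
        n_mut = rng.randint(0, 4)
        for pos in rng.sample(range(len(MITO_ANCHOR)), n_mut):
            genome[pos] = rng.choice([b for b in "ACGT" if b != genome[pos]])
        seq = "".join(genome)
        shift = rng.randrange(len(seq))
        record = SequenceRecord(f"t{trial}", seq[shift:] + seq[:shift])
        query = AnchorQuery(MITO_ANCHOR, 4)
        try:
            outcome = rotate_to_anchor(record, query)
        except AmbiguousAnchorError:
            continue  # random tail may rarely create a second hit at m=4
        prefix = outcome.record.residues[: len(MITO_ANCHOR)]
        assert circular_window_mismatches(outcome.record.residues, 0, MITO_ANCHOR) <= 4
        assert sum(a != b for a, b in zip(prefix, MITO_ANCHOR)) <= 4


def test_record_name_is_first_header_token():
    record = SequenceRecord("NC_012920.1 Homo sapiens mitochondrion", "ACGT")
    assert record.name == "NC_012920.1"
    assert record.length == 4
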