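# Methods

## Problem and model

A circular DNA molecule of length L has L equivalent linearizations per
strand; a deposited sequence is one of the 2L. `seqrotate` maps a set of
such linearizations to a shared representative defined either by a fixed
shift or by the location of a user-chosen anchor string.

Matching is circular Hamming matching: the anchor `a` (length `w`) is
compared with the window starting at every position `p` of the sequence
read modulo L, on the forward sequence and on its reverse complement, and
`p` is a hit when the number of mismatching positions is at most the
budget `m`. The tolerance model is substitutions only — no indels, no
alignment — which is what makes uniqueness a meaningful, cheaply checkable
property. Rotation proceeds only on a unique hit across both searched
strands; "one best hit among several" is treated as ambiguous, because the
contract is that the anchor *identifies* the start, not that it ranks
candidates.

Assumptions worth stating:

- sequences are genuinely circular; rotating a linear sequence with this
  tool scrambles it,
- the anchor is effectively unique in the genome at the chosen budget
  (conserved single-copy regions and primer sites qualify; repeats do not),
- substitution noise dominates at the anchor locus; an indel in the anchor
  region defeats Hamming matching and surfaces as NOT_FOUND.

## Conventions and parameters

- **Coordinates**: 0-based everywhere in the library. `-x` is a 0-based
  shift amount, so `-x 0` is the identity — stated in the CLI help because
  shift-vs-start-at conventions vary across tools. Diagnostic positions
  printed to stderr are 1-based, the convention bioinformatics users read.
- **Mismatch budget** `-m` (default 0) must satisfy `m < w`: at `m >= w`
  every window of every sequence is a hit and every record is ambiguous,
  so the case is rejected at argument parsing.
- **Matching alphabet**: literal, case-insensitive. N matches only N,
  IUPAC ambiguity codes are not expanded, `-` matches only `-`. Wildcard
  semantics would silently change what "unique" means, which is the
  property the whole contract rests on.
- **Case**: preserved in output (soft-masking survives rotation), ignored
  in matching.
- **Reverse hits**: coordinates are reported on the reverse-complemented
  sequence, so the printed position is directly the rotation that will be
  applied after the flip; every successful output presents the anchor on
  the forward strand from residue 1, which is the only orientation that
  makes a downstream multiple alignment coherent.
- **Line width**: output FASTA wraps at 60 columns by default
  (`--line-width` to change); headers are never reformatted.

## Failure contract

Anchor mode is all-or-nothing: verdicts for every record are collected
first, FASTA is written only if the entire file succeeded, and on failure
*every* failing record is reported as `name<TAB>kind[<TAB>hits...]` with
kinds NOT_FOUND, AMBIGUOUS (one `strand:position:mismatches` field per
hit), EMPTY and ANCHOR_TOO_LONG, then the process exits 1. A partially
rotated FASTA silently fed to an aligner is the failure mode this guards
against. Offset mode cannot be ambiguous, so it streams with one record
resident at a time and memory flat in the record count; its only
per-record failure is an empty sequence (a zero-length circle has no
rotation), which aborts the run — records already written stay written,
the cost of streaming.

Exit codes: 0 success; 1 per-record rotation failure; 2 usage error;
3 I/O or input-format error (missing file, corrupt gzip, sequence content
before the first header, an input with zero records).

## Algorithms and numerics

The production matcher accumulates, for each pattern column j, the
vectorized comparison of the cyclically shifted sequence against `a[j]`
(numpy, uint8 views of the upper-cased bytes), giving per-start mismatch
counts in O(L·w) with small constants; anchors are primer-sized and
genomes at most a few hundred kb, so nothing subtler is warranted. Only
starts in [0, L) are enumerated, so origin-spanning hits appear exactly
once and no deduplication is needed. The test oracle solves the same
problem by a different mechanism — explicit string doubling and full
character-by-character counts with no budget — and shares no matching
code, so agreement on randomized instances (including origin-spanning,
reverse-only, zero-hit and saturated `m = w−1` cases) is evidence for
both. There is no floating point anywhere and no randomness in the
library; all generators take explicit seeds.

Reverse complementation maps the full IUPAC set (A↔T, C↔G, R↔Y, K↔M, S, W,
B↔V, D↔H, N, `-`) preserving case; any other byte becomes N (n if
lowercase), so arbitrary input survives a flip without crashing while
clearly marking unknowns.

## Synthetic data generator

`synth.make_genome` emulates the situation the tool exists for: a circular
genome carrying one copy of a known anchor at a known rotation and strand.
The background is i.i.d. with a configurable GC fraction (default 0.45,
a mid-range organelle-like composition); the planted anchor copy receives
exactly `n_mutations` substitutions at seeded positions. Uniqueness is
guaranteed *by construction*: the background is redrawn (up to 50 times)
until the planted copy is the only hit on either strand at
`search_budget` — the budget the cohort will later be searched with, which
matters because a record mutated once but searched at `m = 4` must have no
second window within 4 mismatches anywhere. Ambiguity tests therefore
plant duplicates explicitly. `make_cohort` derives per-record seeds,
rotations, strands and mutation counts from one cohort seed and writes the
FASTA (gzip mtime pinned to 0 so outputs are byte-reproducible) plus a
truth table for assertions.

What the generator does not emulate — and hence what passing tests do not
show about real data: realistic base composition and repeat structure,
indels, anchors that are genuinely multi-copy, and assembly artifacts.
The cohort sizes used in tests and in `scripts/acceptance.py` (200 records
at 16.5 kb with the conserved mammalian mitochondrial anchor at `m = 4`;
50 records at 150 kb with a plant barcode primer at `m = 1`) were chosen
as desk-scale stand-ins for real organelle cohorts at those genome sizes
and search settings.

## Degenerate inputs and edge cases

- Empty sequence: per-record error (no rotation exists).
- Anchor longer than the sequence: per-record error naming the record.
- Anchor equal to the whole sequence: legal; a self-reverse-complementary
  sequence then yields hits on both strands and is correctly ambiguous.
- Genome exactly anchor-sized in the generator: legal, the record is the
  (mutated) anchor; periodic or self-reverse-complementary anchors at tiny
  lengths exhaust the redraw budget and raise, rather than looping.
- Zero-record input: an error at the CLI layer (exit 3), not in the
  parser, which legitimately yields an empty stream.

## Known limitations

- Hamming-only tolerance: one indel in the anchor region defeats the
  search even at a generous budget.
- No multi-copy resolution: the tool refuses ambiguous records rather than
  choosing; that is a design position, not a missing feature.
- Offset-mode streaming can leave a partial output file if an empty record
  aborts the run mid-file.
- The matcher holds one sequence (and its reverse complement) in memory;
  fine for organelles and bacteria, untested for chromosome-scale input.
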