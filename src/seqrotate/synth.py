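"""Deterministic synthetic fixtures: circular genomes with a planted anchor.

Each genome is an i.i.d. random background (with a chosen GC fraction) into
which a copy of the anchor, carrying an exact number of substitution
mutations, is spliced at a known rotation and strand. Uniqueness of the
planted occurrence — within the mismatch budget the genome will later be
searched with, on both strands — is guaranteed by construction: the
background is redrawn (bounded retries) whenever a spurious hit appears.
Mutations are substitutions only, matching the Hamming tolerance model of
the matcher; indels would conflate matcher limits with fixture noise.
"""

from __future__ import annotations

import gzip
import random
from contextlib import contextmanager
from dataclasses import dataclass, replace
from pathlib import Path
from typing import IO, Iterator, Optional, Union

import numpy as np

from .core import (
    FORWARD,
    REVERSE,
    AnchorHit,
    AnchorQuery,
    SequenceRecord,
    Strand,
    find_anchor_hits,
    reverse_complement,
)
from .io import write_fasta

__all__ = ["SynthSpec", "CohortRow", "make_genome", "make_cohort"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_MAX_REDRAWS = 50


@dataclass(frozen=True)
class SynthSpec:
    """Parameters for one synthetic circular genome.

    ``n_mutations`` substitutions are applied to the planted anchor copy;
    ``search_budget`` is the mismatch budget the genome must stay unique
    under (defaults to ``n_mutations``) — set it to the ``-m`` value the
    cohort will be searched with. ``rotation`` is the offset at which the
    planted anchor starts, on the forward sequence for strand=forward and
    on the reverse-complemented sequence for strand=reverse, so it is
    exactly the offset a successful anchor rotation must recover.
    """

    genome_length: int
    anchor: str
    n_mutations: int = 0
    rotation: int = 0
    strand: Strand = FORWARD
    seed: int = 0
    gc_fraction: float = 0.45
    search_budget: Optional[int] = None

    def __post_init__(self) -> None:
        w = len(self.anchor)
        if w < 1:
            raise ValueError("anchor must be non-empty")
        if self.genome_length < w:
            raise ValueError("genome_length must be >= anchor length")
        if not 0 <= self.n_mutations < w:
            raise ValueError("n_mutations must be in [0, anchor length)")
        if not 0 <= self.rotation < self.genome_length:
            raise ValueError("rotation must be in [0, genome_length)")
        if self.strand not in (FORWARD, REVERSE):
            raise ValueError(f"unknown strand {self.strand!r}")
        if not 0.0 < self.gc_fraction < 1.0:
            raise ValueError("gc_fraction must be in (0, 1)")
        budget = self.effective_budget
        if not self.n_mutations <= budget < w:
            raise ValueError(
                "search_budget must be in [n_mutations, anchor length)"
            )

    @property
    def effective_budget(self) -> int:
        return (
            self.n_mutations if self.search_budget is None else self.search_budget
        )


def _mutate_anchor(anchor: str, n_mutations: int, rng: np.random.Generator) -> str:
    """Apply exactly n_mutations substitutions at distinct positions."""
    seq = list(anchor.upper())
    positions = rng.choice(len(seq), size=n_mutations, replace=False)
    for pos in positions:
        choices = [b for b in "ACGT" if b != seq[pos]]
        seq[pos] = choices[int(rng.integers(len(choices)))]
    return "".join(seq)


def _random_background(n: int, gc: float, rng: np.random.Generator) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    draw = rng.choice(_BASES, size=n, p=probs)
    return draw.tobytes().decode("ascii")


def make_genome(
    spec: SynthSpec, name: str = "synth"
) -> tuple[SequenceRecord, AnchorHit]:
    """Generate one genome plus the hit an anchor rotation must recover.

    The returned record carries the mutated anchor at ``spec.rotation`` on
    the requested strand and nothing else within ``spec.search_budget``
    mismatches of the anchor on either strand. Raises RuntimeError if the
    redraw budget is exhausted (pathological specs only, e.g. anchors that
    overlap their own reverse complement at small genome lengths).
    """
    rng = np.random.default_rng(spec.seed)
    w = len(spec.anchor)
    budget = spec.effective_budget
    mutated = _mutate_anchor(spec.anchor, spec.n_mutations, rng)
    expected_only_hit = AnchorHit(0, FORWARD, spec.n_mutations)
    query = AnchorQuery(spec.anchor, budget)

    for _ in range(_MAX_REDRAWS):
        background = _random_background(
            spec.genome_length - w, spec.gc_fraction, rng
        )
        unrotated = mutated + background
        probe = SequenceRecord(name, unrotated)
        if find_anchor_hits(probe, query, search_reverse=True) == [expected_only_hit]:
            break
    else:
        raise RuntimeError(
            f"could not build a genome with a unique planted anchor after "
            f"{_MAX_REDRAWS} background redraws (spec: {spec})"
        )

    k = spec.rotation
    oriented = unrotated[-k:] + unrotated[:-k] if k else unrotated
    if spec.strand == REVERSE:
        oriented = reverse_complement(oriented)
    record = SequenceRecord(name, oriented)
    return record, AnchorHit(spec.rotation, spec.strand, spec.n_mutations)


@dataclass(frozen=True)
class CohortRow:
    """One truth-table entry: what the generator planted for a record."""

    name: str
    rotation: int
    strand: Strand
    mutations: int


@contextmanager
def _open_out(path: Union[str, Path]) -> Iterator[IO[str]]:
    path = Path(path)
    if path.suffix == ".gz":
        import io as _stdio

        # mtime pinned to 0 so identical cohorts are byte-identical on disk
        with open(path, "wb") as raw:
            with gzip.GzipFile(filename="", fileobj=raw, mode="wb", mtime=0) as gz:
                with _stdio.TextIOWrapper(gz) as handle:
                    yield handle
    else:
        with open(path, "w") as handle:
            yield handle


def make_cohort(
    n: int,
    base_spec: SynthSpec,
    seed: int,
    fasta_path: Union[str, Path],
    truth_path: Union[str, Path],
) -> list[CohortRow]:
    """Write an n-record FASTA cohort plus a tab-separated truth table.

    Per-record seeds, rotations and strands are drawn from ``seed``;
    mutation counts are uniform in [0, base_spec.n_mutations]. Output is
    byte-for-byte reproducible for identical arguments; a ``.gz`` FASTA
    path is written gzip-compressed. Returns the truth rows
    (also written to ``truth_path`` with a header line).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = random.Random(seed)
    rows: list[CohortRow] = []
    records: list[SequenceRecord] = []
    for i in range(n):
        spec_i = replace(
            base_spec,
            seed=rng.randrange(2**31),
            rotation=rng.randrange(base_spec.genome_length),
            strand=rng.choice([FORWARD, REVERSE]),
            n_mutations=rng.randint(0, base_spec.n_mutations),
            search_budget=base_spec.effective_budget,
        )
        record, hit = make_genome(spec_i, name=f"synth_{i:04d}")
        records.append(record)
        rows.append(CohortRow(record.name, hit.start, hit.strand, hit.mismatches))

    with _open_out(fasta_path) as handle:
        write_fasta(records, handle)
    with open(truth_path, "w") as handle:
        handle.write("name\trotation\tstrand\tmutations\n")
        for row in rows:
            handle.write(
                f"{row.name}\t{row.rotation}\t{row.strand}\t{row.mutations}\n"
            )
    return rows
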