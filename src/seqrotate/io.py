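"""Streaming FASTA reading (plain or gzip, autodetected) and writing.

Records are yielded lazily, one at a time, matching the per-sequence
processing model: a many-thousand-record file is never fully resident.
Compression is detected from the gzip magic bytes, never the file
extension, so renamed files behave correctly.
"""

from __future__ import annotations

import gzip
import sys
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

from .core import SequenceRecord

__all__ = ["FastaFormatError", "read_fasta", "write_fasta"]

_GZIP_MAGIC = b"\x1f\x8b"

Source = Union[str, Path, IO[str], IO[bytes]]


class FastaFormatError(ValueError):
    """Malformed FASTA input (e.g. sequence content before the first '>')."""


def _open_text(source: Source) -> tuple[IO[str], bool]:
    """Resolve a path / '-' / file object into a text handle.

    Returns (handle, caller_should_close). Gzip is detected by peeking at
    the first two bytes of binary input.
    """
    if isinstance(source, (str, Path)):
        if str(source) == "-":
            return _wrap_binary(sys.stdin.buffer), False
        return _wrap_binary(open(source, "rb")), True
    if not hasattr(source, "read"):
        raise TypeError(f"cannot read FASTA from {source!r}")
    if isinstance(source.read(0), bytes):
        return _wrap_binary(source), False  # binary file object
    # Already a text handle (e.g. io.StringIO) — use as-is.
    return source, False  # type: ignore[return-value]


def _wrap_binary(handle: IO[bytes]) -> IO[str]:
    import io as _stdio

    buffered = handle if hasattr(handle, "peek") else _stdio.BufferedReader(handle)
    if buffered.peek(2)[:2] == _GZIP_MAGIC:
        return _stdio.TextIOWrapper(
            gzip.GzipFile(fileobj=buffered), encoding="latin-1"
        )
    return _stdio.TextIOWrapper(buffered, encoding="latin-1")


def read_fasta(source: Source) -> Iterator[SequenceRecord]:
    """Yield one SequenceRecord per FASTA entry, lazily, in file order.

    ``source`` may be a path, '-' for stdin, or an open text/binary handle.
    Multi-line bodies are concatenated; surrounding whitespace (including
    CRLF endings) is stripped from each body line. Raises FastaFormatError
    on sequence content before the first header. An empty file yields zero
    records (callers decide whether that is an error).
    """
    handle, should_close = _open_text(source)
    try:
        description: str | None = None
        chunks: list[str] = []
        for line in handle:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if description is not None:
                    yield SequenceRecord(description, "".join(chunks))
                description = line[1:]
                chunks = []
            else:
                if description is None:
                    raise FastaFormatError(
                        "sequence content before the first '>' header"
                    )
                chunks.append(line)
        if description is not None:
            yield SequenceRecord(description, "".join(chunks))
    finally:
        if should_close:
            handle.close()


def write_fasta(
    records: Iterable[SequenceRecord],
    handle: IO[str],
    width: int = 60,
) -> None:
    """Write records as FASTA, wrapping bodies at ``width`` columns.

    Headers are emitted verbatim ('>' + description); line endings are
    always LF. Round-trips through read_fasta reproduce names, descriptions
    and residues exactly.
    """
    if width < 1:
        raise ValueError("line width must be >= 1")
    for record in records:
        handle.write(f">{record.description}\n")
        residues = record.residues
        for i in range(0, len(residues), width):
            handle.write(residues[i : i + width])
            handle.write("\n")
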