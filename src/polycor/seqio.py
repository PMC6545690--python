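"""Paired-end FASTQ input/output with strict pairing and ordering guarantees.

Reads are handled as :class:`ReadPair` objects addressed by their 0-based
ordinal in the input.  Pairing is positional: record *i* of file 1 mates
record *i* of file 2; any ``/1`` / ``/2`` identifier suffixes are ignored
for pairing purposes.  Output preserves input order and record count, so
reading back a written file reproduces the original pairs exactly.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from itertools import zip_longest
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "ReadRecord",
    "ReadPair",
    "FastqFormatError",
    "PairingError",
    "read_paired_fastq",
    "write_paired_fastq",
    "merge_corrected",
]

_VALID_BASES = frozenset("ACGTN")


class FastqFormatError(ValueError):
    """A FASTQ record violates the format contract (e.g. seq/qual length)."""


class PairingError(ValueError):
    """The two input files do not contain the same number of records."""


@dataclass(frozen=True)
class ReadRecord:
    """A single read: identifier, sequence over {A,C,G,T,N}, phred+33 quality."""

    id: str
    seq: str
    qual: str
    mate: int

    def __post_init__(self) -> None:
        if not self.seq:
            raise FastqFormatError(f"empty sequence for read {self.id!r}")
        if len(self.qual) != len(self.seq):
            raise FastqFormatError(
                f"seq/qual length mismatch for read {self.id!r}: "
                f"{len(self.seq)} vs {len(self.qual)}"
            )
        if self.mate not in (1, 2):
            raise ValueError(f"mate must be 1 or 2, got {self.mate}")
        if not _VALID_BASES.issuperset(self.seq):
            bad = sorted(set(self.seq) - _VALID_BASES)
            raise FastqFormatError(f"invalid bases {bad} in read {self.id!r}")


@dataclass(frozen=True)
class ReadPair:
    """A mated pair of reads addressed by its 0-based position in the input."""

    ordinal: int
    r1: ReadRecord
    r2: ReadRecord

    def __post_init__(self) -> None:
        if self.r1.mate != 1 or self.r2.mate != 2:
            raise ValueError("r1 must have mate=1 and r2 mate=2")


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _iter_records(path, mate: int) -> Iterable[ReadRecord]:
    with _open_text(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            yield ReadRecord(id=title.split()[0], seq=seq.upper(), qual=qual, mate=mate)


def read_paired_fastq(path1, path2=None, *, interleaved: bool = False) -> list[ReadPair]:
    """Read paired-end FASTQ from two files, or one interleaved file.

    Pairs are returned in file order with ``ordinal`` equal to the record
    index.  Gzip-compressed input (``.gz`` suffix) is accepted.

    Raises
    ------
    PairingError
        If the two files hold different record counts (or an interleaved
        file holds an odd number of records).
    FastqFormatError
        If a record violates the FASTQ contract.
    """
    pairs: list[ReadPair] = []
    if interleaved or path2 is None:
        it = _iter_records(path1, 1)
        for ordinal, rec1 in enumerate(it):
            try:
                raw2 = next(iter(it))
            except StopIteration:
                raise PairingError(
                    f"interleaved file {path1} holds an odd number of records"
                ) from None
            rec2 = ReadRecord(id=raw2.id, seq=raw2.seq, qual=raw2.qual, mate=2)
            pairs.append(ReadPair(ordinal=ordinal, r1=rec1, r2=rec2))
        return pairs

    sentinel = object()
    for ordinal, (rec1, rec2) in enumerate(
        zip_longest(_iter_records(path1, 1), _iter_records(path2, 2), fillvalue=sentinel)
    ):
        if rec1 is sentinel or rec2 is sentinel:
            raise PairingError(
                f"record-count mismatch between {path1} and {path2} at record {ordinal}"
            )
        pairs.append(ReadPair(ordinal=ordinal, r1=rec1, r2=rec2))
    return pairs


def _format_record(rec: ReadRecord) -> str:
    return f"@{rec.id}\n{rec.seq}\n+\n{rec.qual}\n"


def write_paired_fastq(pairs: Sequence[ReadPair], path1, path2=None, *, interleaved: bool = False) -> None:
    """Write pairs to two FASTQ files (or one interleaved file, in r1,r2 order).

    Pairs must be ordered by ordinal; output preserves that order so that
    ``read_paired_fastq`` on the result reproduces the input.
    """
    if interleaved or path2 is None:
        with _open_text(path1, "wt") as h:
            for p in pairs:
                h.write(_format_record(p.r1))
                h.write(_format_record(p.r2))
        return
    with _open_text(path1, "wt") as h1, _open_text(path2, "wt") as h2:
        for p in pairs:
            h1.write(_format_record(p.r1))
            h2.write(_format_record(p.r2))


def merge_corrected(
    original: Sequence[ReadPair], corrected: Mapping[int, ReadPair]
) -> list[ReadPair]:
    """Substitute corrected pairs into the original sequence by ordinal.

    Pairs absent from ``corrected`` pass through untouched; the output has
    the same length and order as ``original``.

    Raises
    ------
    KeyError
        If ``corrected`` holds an ordinal not present in ``original``.
    """
    known = {p.ordinal for p in original}
    unknown = set(corrected) - known
    if unknown:
        raise KeyError(f"corrected ordinals not present in input: {sorted(unknown)[:5]}")
    return [corrected.get(p.ordinal, p) for p in original]
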