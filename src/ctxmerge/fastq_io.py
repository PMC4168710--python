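"""FASTQ input/output and read preprocessing.

Reads are modelled as a called base sequence over {A,C,G,T,N} with one
Phred-scaled quality per base (Q = -10*log10 p, p the probability the call is
wrong).  Paired files are streamed record-by-record; gzip compression is
detected from the file's magic bytes, so ``.fastq`` and ``.fastq.gz`` are both
accepted with any name.
"""

from __future__ import annotations

import gzip
import io
import warnings
from dataclasses import dataclass
from typing import IO, Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "SequencingRead",
    "ReadPair",
    "FastqFormatError",
    "decode_quality",
    "encode_quality",
    "phred_to_error_prob",
    "reverse_complement_read",
    "read_fastq",
    "read_paired_fastq",
    "write_fastq",
]

MAX_PHRED = 93

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGTN")


class FastqFormatError(ValueError):
    """Malformed FASTQ input (bad record structure, alphabet or quality)."""


@dataclass
class SequencingRead:
    """A called sequence with per-base Phred qualities.

    Invariants: ``len(sequence) == len(qualities)``, every quality in
    [0, 93], alphabet exactly {A,C,G,T,N} (upper-cased on construction
    via :func:`make_read`).
    """

    identifier: str
    sequence: str
    qualities: list[int]

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadPair:
    """A synchronized forward/reverse mate pair."""

    forward: SequencingRead
    reverse: SequencingRead


def decode_quality(char: str, offset: int = 33) -> int:
    """Decode one ASCII quality character to its Phred value."""
    q = ord(char) - offset
    if not 0 <= q <= MAX_PHRED:
        raise FastqFormatError(
            f"quality character {char!r} out of range for Phred+{offset}"
        )
    return q


def encode_quality(q: int, offset: int = 33) -> str:
    """Encode a Phred value to one ASCII character."""
    if not 0 <= q <= MAX_PHRED:
        raise ValueError(f"Phred value {q} outside [0, {MAX_PHRED}]")
    return chr(q + offset)


def phred_to_error_prob(q: int) -> float:
    """Error probability p for Phred score q: p = 10**(-q/10)."""
    if q < 0:
        raise ValueError("Phred score must be >= 0")
    return 10.0 ** (-q / 10.0)


def make_read(identifier: str, sequence: str, qualities: list[int]) -> SequencingRead:
    """Validate and build a :class:`SequencingRead` (upper-cases the sequence)."""
    seq = sequence.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        raise FastqFormatError(
            f"read {identifier!r}: invalid base(s) {sorted(bad)} "
            "(alphabet is A,C,G,T,N)"
        )
    if len(seq) != len(qualities):
        raise FastqFormatError(
            f"read {identifier!r}: {len(seq)} bases but {len(qualities)} qualities"
        )
    return SequencingRead(identifier, seq, qualities)


def reverse_complement_read(read: SequencingRead) -> SequencingRead:
    """Reverse-complement a read; qualities are reversed alongside the bases.

    Base i of the output is the Watson-Crick complement of base n-i+1 of the
    input (N maps to N); quality i of the output is quality n-i+1 of the
    input.  The operation is an involution.
    """
    return SequencingRead(
        read.identifier,
        read.sequence.translate(_COMPLEMENT)[::-1],
        read.qualities[::-1],
    )


def _open_maybe_gzip(path: str) -> IO[str]:
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="ascii")
    return open(path, "rt", encoding="ascii")


def read_fastq(path: str, offset: int = 33) -> Iterator[SequencingRead]:
    """Stream validated reads from a FASTQ file (plain or gzipped)."""
    with _open_maybe_gzip(path) as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                identifier = title.split(None, 1)[0] if title else ""
                qualities = [decode_quality(c, offset) for c in qual]
                yield make_read(identifier, seq, qualities)
        except ValueError as exc:  # Biopython reports truncated/odd records
            if isinstance(exc, FastqFormatError):
                raise
            raise FastqFormatError(f"{path}: {exc}") from exc


def mate_core(identifier: str) -> str:
    """Identifier with a trailing /1 or /2 mate suffix stripped."""
    if len(identifier) > 1 and identifier[-2] == "/" and identifier[-1] in "12":
        return identifier[:-2]
    return identifier


def read_paired_fastq(
    forward_path: str,
    reverse_path: str,
    offset: int = 33,
    strict_pairing: bool = False,
) -> Iterator[ReadPair]:
    """Stream synchronized mate pairs from two FASTQ files.

    Pairing is positional (record i with record i).  Identifier agreement
    after stripping the mate suffix is checked: a mismatch warns, or raises
    when ``strict_pairing`` is set.  Unequal record counts raise.
    """
    fwd = read_fastq(forward_path, offset)
    rev = read_fastq(reverse_path, offset)
    index = 0
    sentinel = object()
    while True:
        f = next(fwd, sentinel)
        r = next(rev, sentinel)
        if f is sentinel and r is sentinel:
            return
        if f is sentinel or r is sentinel:
            longer = reverse_path if f is sentinel else forward_path
            raise FastqFormatError(
                f"unequal record counts: extra record {index + 1} in {longer}"
            )
        index += 1
        if mate_core(f.identifier) != mate_core(r.identifier):
            msg = (
                f"record {index}: identifiers {f.identifier!r} and "
                f"{r.identifier!r} disagree"
            )
            if strict_pairing:
                raise FastqFormatError(msg)
            warnings.warn(msg, stacklevel=2)
        yield ReadPair(f, r)


def write_fastq(reads: Iterable[SequencingRead], path: str, offset: int = 33) -> int:
    """Write 4-line FASTQ records; returns the record count.

    Round-trip read -> write -> read is the identity on identifier,
    sequence and qualities.
    """
    count = 0
    with open(path, "w", encoding="ascii") as handle:
        for read in reads:
            qual = "".join(encode_quality(q, offset) for q in read.qualities)
            handle.write(f"@{read.identifier}\n{read.sequence}\n+\n{qual}\n")
            count += 1
    return count
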