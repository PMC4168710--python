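"""Exact k-mer counting over the preprocessed read population.

The table maps every k-length substring over {A,C,G,T} seen in any
preprocessed read (forward reads plus reverse-complemented reverse reads,
which after preprocessing represent the same fragment strand and are pooled
into one table) to its occurrence count.  Windows containing N are skipped:
an indecisive call carries no context information.  Counting is
non-canonical — a k-mer and its reverse complement are distinct keys.
"""

from __future__ import annotations

from collections import Counter
from typing import IO, Iterable

__all__ = ["KmerTable", "build_kmer_table"]

MAX_K = 31


class KmerTable:
    """Exact counts of k-mers; absent keys (and any N-containing query) count 0."""

    def __init__(self, k: int):
        if not 1 <= k <= MAX_K:
            raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
        self.k = k
        self._counts: Counter[str] = Counter()

    def add_read(self, sequence: str) -> None:
        """Count every N-free k-window of one read (shorter reads add nothing)."""
        k = self.k
        counts = self._counts
        n = len(sequence)
        if "N" not in sequence:
            for i in range(n - k + 1):
                counts[sequence[i : i + k]] += 1
            return
        # restart the scan after each N so no window spans one
        for chunk in sequence.split("N"):
            for i in range(len(chunk) - k + 1):
                counts[chunk[i : i + k]] += 1

    def lookup(self, kmer: str) -> int:
        if len(kmer) != self.k:
            raise ValueError(f"query length {len(kmer)} != k={self.k}")
        return self._counts.get(kmer, 0)

    def __len__(self) -> int:
        return len(self._counts)

    def total(self) -> int:
        """Sum of all stored counts (= number of counted windows)."""
        return sum(self._counts.values())

    def dump(self, handle: IO[str]) -> None:
        """Debug dump as sorted two-column text (kmer, count)."""
        for kmer in sorted(self._counts):
            handle.write(f"{kmer}\t{self._counts[kmer]}\n")

    @classmethod
    def load(cls, handle: IO[str], k: int) -> "KmerTable":
        table = cls(k)
        for line in handle:
            kmer, count = line.split("\t")
            if len(kmer) != k:
                raise ValueError(f"k-mer {kmer!r} has length != {k}")
            table._counts[kmer] = int(count)
        return table


def build_kmer_table(sequences: Iterable[str], k: int) -> KmerTable:
    """Build the count table from an iterable of (preprocessed) sequences.

    The result is independent of input order.
    """
    table = KmerTable(k)
    for seq in sequences:
        table.add_read(seq)
    return table
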