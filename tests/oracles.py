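"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plainly as possible (pure-Python scans and
dictionaries) and never calls the code paths it checks.
"""

from __future__ import annotations

import math
from collections import Counter


def brute_force_mismatches(x: str, y: str, b: int) -> tuple[int, int]:
    """(mismatches, overlap length) for offset b; flags only {ACGT}x{ACGT} diffs."""
    length = min(len(x) - b + 1, len(y))
    mism = 0
    for t in range(length):
        cx, cy = x[b - 1 + t], y[t]
        if cx in "ACGT" and cy in "ACGT" and cx != cy:
            mism += 1
    return mism, length


def brute_force_best_overlap(x: str, y: str, omega: int):
    """Scan every offset; strict improvement keeps the smallest offset.

    Returns (b, length, mismatches, ratio) or None when no offset is valid.
    """
    best = None
    best_ratio = math.inf
    for b in range(1, len(x) - omega + 2):
        if min(len(x) - b + 1, len(y)) < omega:
            continue
        mism, length = brute_force_mismatches(x, y, b)
        ratio = mism / length
        if ratio < best_ratio:
            best_ratio = ratio
            best = (b, length, mism, ratio)
    return best


def brute_force_kmer_counts(sequences, k: int) -> dict[str, int]:
    """Dictionary-of-substrings counter; windows containing N are skipped."""
    counts: Counter[str] = Counter()
    for seq in sequences:
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if "N" not in window:
                counts[window] += 1
    return dict(counts)


def brute_force_context_windows(
    x: str, y: str, i: int, i_prime: int, k: int
) -> list[tuple[int, str, str]]:
    """Enumerate the surviving (j, X-window, Y-window) triples for a mismatch.

    Mirrors the published window rules literally: skip a window underrunning
    the left end of either read, stop at one overrunning the right end of
    either read or whose last position is an uncorrected downstream mismatch.
    """
    out = []
    for j in range(1, k + 1):
        if i - k + j < 1 or i_prime - k + j < 1:
            continue
        if i + j - 1 > len(x) or i_prime + j - 1 > len(y):
            break
        if j > 1 and x[i + j - 2] != y[i_prime + j - 2]:
            break
        out.append(
            (j, x[i - k + j - 1 : i + j - 1], y[i_prime - k + j - 1 : i_prime + j - 1])
        )
    return out
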