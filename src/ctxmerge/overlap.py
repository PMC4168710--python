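"""Best-overlap detection between a forward read and a preprocessed reverse read.

The reverse read Y (already reverse-complemented) is slid to the right along
the forward read X; for each candidate start offset b (1-based position in X)
the mismatch ratio over the overlapped positions is computed and the offset
with the strictly lowest ratio wins.  Ties keep the smallest b, i.e. the
longest overlap, because the running minimum is only replaced on strict
improvement.  A pair whose best ratio exceeds the give-up threshold gamma is
left unmerged.

Positions where either base is N are excluded from the mismatch count but
still included in the overlap length: the denominator is purely positional,
while an indecisive call is not evidence of disagreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "OverlapStatus",
    "OverlapResult",
    "count_mismatches",
    "find_best_overlap",
    "apply_giveup",
]

_N_CODE = ord("N")


class OverlapStatus:
    ACCEPTED = "accepted"
    ABANDONED = "abandoned_mismatch_ratio"
    NO_VALID_OFFSET = "no_valid_offset"


@dataclass(frozen=True)
class OverlapResult:
    """Chosen shift of Y against X.

    ``offset`` is the 1-based index b in X where the overlap starts;
    ``overlap_length`` = min(len(X) - b + 1, len(Y)).
    """

    offset: int
    overlap_length: int
    mismatch_count: int
    mismatch_ratio: float
    status: str


def count_mismatches(x: str, y: str, b: int) -> int:
    """Mismatching overlap positions for offset b; one-sided or double N never counts."""
    if not 1 <= b <= len(x):
        raise ValueError(f"offset {b} outside [1, {len(x)}]")
    length = min(len(x) - b + 1, len(y))
    mism = 0
    for j in range(length):
        cx = x[b - 1 + j]
        cy = y[j]
        if cx != cy and cx != "N" and cy != "N":
            mism += 1
    return mism


def find_best_overlap(x: str, y: str, omega: int) -> OverlapResult:
    """Scan offsets b in [1, len(X) - omega + 1] for the lowest mismatch ratio.

    Returns status ``no_valid_offset`` when the candidate range is empty
    (either read shorter than omega).  The scan is vectorised per offset but
    equivalent to the naive position-by-position comparison.
    """
    if omega < 1:
        raise ValueError("omega must be >= 1")
    if len(x) < omega or len(y) < omega:
        return OverlapResult(0, 0, 0, math.inf, OverlapStatus.NO_VALID_OFFSET)

    xa = np.frombuffer(x.encode("ascii"), dtype=np.uint8)
    ya = np.frombuffer(y.encode("ascii"), dtype=np.uint8)
    n_x, n_y = len(xa), len(ya)

    best_ratio = math.inf
    best_b = 0
    best_len = 0
    best_mism = 0
    for b in range(1, n_x - omega + 2):
        length = min(n_x - b + 1, n_y)
        xs = xa[b - 1 : b - 1 + length]
        ys = ya[:length]
        mism = int(
            np.count_nonzero((xs != ys) & (xs != _N_CODE) & (ys != _N_CODE))
        )
        ratio = mism / length
        if ratio < best_ratio:
            best_ratio = ratio
            best_b = b
            best_len = length
            best_mism = mism
    return OverlapResult(best_b, best_len, best_mism, best_ratio, OverlapStatus.ACCEPTED)


def apply_giveup(result: OverlapResult, gamma: float) -> OverlapResult:
    """Mark the result abandoned iff its mismatch ratio strictly exceeds gamma."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must be in [0, 1]")
    if result.status != OverlapStatus.ACCEPTED:
        return result
    if result.mismatch_ratio > gamma:
        return replace(result, status=OverlapStatus.ABANDONED)
    return result
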