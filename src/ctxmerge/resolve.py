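"""Two-pass mismatch resolution inside an accepted overlap.

Pass 1 (quality pass): a mismatch whose Phred scores differ by more than the
threshold delta is resolved in favour of the higher-scoring base — a large
quality gap is decisive on its own.  One-sided N is overwritten by the
informative base regardless of delta; double-N positions are skipped.

Pass 2 (context pass): for each remaining mismatch at X(i)/Y(i'), up to k
progressively shifted k-mer windows ending at or after the mismatch are
compared between the two reads via their counts in the k-mer table.  Each
window casts a vote for the read whose window is more frequent in the input
population; the forward base wins only on a strict majority (a linear
opinion pool thresholded at 1/2), otherwise the reverse base wins.  The
count ratio approximates the posterior odds that the forward base is the
correct one, under the assumption that forward and reverse reads are equally
reliable a priori.

Both passes scan the overlap left to right and overwrite the loser's base
AND quality with the winner's, so windows extending leftward from a later
mismatch see already-corrected bases.
"""

from __future__ import annotations

from dataclasses import dataclass

from .kmer import KmerTable

__all__ = [
    "MergeParams",
    "ContextVote",
    "quality_pass",
    "collect_context_votes",
    "decide",
    "context_pass",
]


@dataclass(frozen=True)
class MergeParams:
    """User parameters of the merger.

    k: context k-mer size (bp); omega: minimum overlap length (bp);
    gamma: give-up mismatch-ratio threshold; delta: Phred-difference
    threshold above which qualities alone decide a mismatch;
    quality_weighted_vote: scale each side's window count by that base's
    error probability 10**(-Q/10) before comparing (off by default — the
    plain count comparison is the headline configuration; the weighted
    variant makes a negligible practical difference).
    """

    k: int = 17
    omega: int = 10
    gamma: float = 0.5
    delta: int = 19
    quality_weighted_vote: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.omega < 1:
            raise ValueError("omega must be >= 1")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")


@dataclass(frozen=True)
class ContextVote:
    """One window's count comparison: j in [1, k], vote in {forward, reverse, none}."""

    j: int
    forward_count: int
    reverse_count: int
    vote: str


def quality_pass(
    x: list[str],
    q_x: list[int],
    y: list[str],
    q_y: list[int],
    b: int,
    delta: int,
) -> None:
    """Resolve overlap mismatches whose quality difference exceeds delta, in place.

    Scans overlap positions left to right.  ``b`` is the 1-based overlap
    start in X.  Differences with \\|dQ\\| <= delta are left for the context
    pass.  If exactly one base is N the other overwrites it regardless of
    delta; double-N positions are skipped.
    """
    length = min(len(x) - b + 1, len(y))
    for t in range(length):
        i = b - 1 + t  # 0-based in X
        if x[i] == y[t]:
            continue
        if x[i] == "N" and y[t] == "N":
            continue
        if x[i] == "N":
            x[i] = y[t]
            q_x[i] = q_y[t]
        elif y[t] == "N":
            y[t] = x[i]
            q_y[t] = q_x[i]
        elif q_x[i] - q_y[t] > delta:
            y[t] = x[i]
            q_y[t] = q_x[i]
        elif q_y[t] - q_x[i] > delta:
            x[i] = y[t]
            q_x[i] = q_y[t]


def collect_context_votes(
    x: list[str] | str,
    y: list[str] | str,
    i: int,
    i_prime: int,
    table: KmerTable,
    q_x_i: int | None = None,
    q_y_i: int | None = None,
    quality_weighted: bool = False,
) -> list[ContextVote]:
    """Evaluate the k context windows for the mismatch at X(i)/Y(i').

    ``i`` and ``i_prime`` are 1-based.  Window j covers X(i-k+j : i+j-1) and
    Y(i'-k+j : i'+j-1).  A window underrunning the left boundary of either
    read is skipped; the scan stops at a window overrunning the right
    boundary of either read, or at an uncorrected downstream mismatch
    (j > 1 and X(i+j-1) != Y(i'+j-1)), whose bases cannot yet be trusted.

    With ``quality_weighted`` set, the forward count is scaled by
    10**(-q_x_i/10) and the reverse count by 10**(-q_y_i/10) before the
    comparison; the raw counts are still reported in the votes.
    """
    k = table.k
    xs = "".join(x) if not isinstance(x, str) else x
    ys = "".join(y) if not isinstance(y, str) else y
    if quality_weighted:
        if q_x_i is None or q_y_i is None:
            raise ValueError("quality_weighted voting needs both base qualities")
        w_f = 10.0 ** (-q_x_i / 10.0)
        w_r = 10.0 ** (-q_y_i / 10.0)
    votes: list[ContextVote] = []
    for j in range(1, k + 1):
        lo_x = i - k + j  # 1-based window start in X
        lo_y = i_prime - k + j
        if lo_x < 1 or lo_y < 1:
            continue
        hi_x = i + j - 1  # 1-based window end
        hi_y = i_prime + j - 1
        if hi_x > len(xs) or hi_y > len(ys):
            break
        if j > 1 and xs[hi_x - 1] != ys[hi_y - 1]:
            break
        fc = table.lookup(xs[lo_x - 1 : hi_x])
        rc = table.lookup(ys[lo_y - 1 : hi_y])
        f_score: float = fc * w_f if quality_weighted else fc
        r_score: float = rc * w_r if quality_weighted else rc
        if f_score > r_score:
            vote = "forward"
        elif r_score > f_score:
            vote = "reverse"
        else:
            vote = "none"
        votes.append(ContextVote(j, fc, rc, vote))
    return votes


def decide(votes: list[ContextVote]) -> str:
    """Majority decision: forward iff strictly more forward votes, else reverse.

    Ties and the empty vote set go to the reverse read.
    """
    fwd = sum(1 for v in votes if v.vote == "forward")
    rev = sum(1 for v in votes if v.vote == "reverse")
    return "forward" if fwd > rev else "reverse"


def context_pass(
    x: list[str],
    q_x: list[int],
    y: list[str],
    q_y: list[int],
    b: int,
    table: KmerTable,
    params: MergeParams,
    decision_log: list | None = None,
) -> None:
    """Resolve every remaining overlap mismatch by context voting, in place.

    Must run after :func:`quality_pass`.  Winners overwrite the loser's base
    and quality, so downstream windows extend over corrected bases.  After
    this pass every overlap position matches or is double-N.  When
    ``decision_log`` is given, (i, i', votes, winner) tuples are appended.
    """
    length = min(len(x) - b + 1, len(y))
    for t in range(length):
        i = b - 1 + t
        if x[i] == y[t]:
            continue
        if x[i] == "N" and y[t] == "N":
            continue
        votes = collect_context_votes(
            x,
            y,
            i + 1,
            t + 1,
            table,
            q_x_i=q_x[i],
            q_y_i=q_y[t],
            quality_weighted=params.quality_weighted_vote,
        )
        winner = decide(votes)
        if winner == "forward":
            y[t] = x[i]
            q_y[t] = q_x[i]
        else:
            x[i] = y[t]
            q_x[i] = q_y[t]
        if decision_log is not None:
            decision_log.append((i + 1, t + 1, votes, winner))
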