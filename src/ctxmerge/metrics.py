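"""Evaluation of merge outcomes against simulated truth.

A merge attempt on a pair either produces an elongated read or leaves the
pair unmerged.  Against known truth, a merged read is *correct* iff it is
identical — same length, same bases — to the fragment it was cut from.
Scoring treats correct merges as true positives, incorrect merges as false
positives and unmerged pairs as false negatives:

    accuracy  = correct / total
    precision = correct / merges
    recall    = correct / (correct + unmerged)
    F1        = 2 * precision * recall / (precision + recall)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .fastq_io import SequencingRead, mate_core
from .pipeline import MergeOutcome
from .simulate import TruthRecord

__all__ = [
    "EvalCounts",
    "MetricSet",
    "classify_merge",
    "compute_metrics",
    "percent_change",
    "evaluate_merged_reads",
]


@dataclass(frozen=True)
class EvalCounts:
    """(total input pairs, merged pairs, correct merges); 0 <= correct <= merges <= total."""

    total: int
    merges: int
    correct: int

    def __post_init__(self) -> None:
        if not 0 <= self.correct <= self.merges <= self.total:
            raise ValueError(
                f"need 0 <= correct <= merges <= total, got {self}"
            )


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    precision: float
    recall: float
    f1: float


def classify_merge(outcome: MergeOutcome, truth: TruthRecord) -> str:
    """'correct', 'incorrect' or 'unmerged' for one outcome vs its truth."""
    if not outcome.is_merged:
        return "unmerged"
    assert outcome.merged is not None
    if outcome.merged.sequence == truth.fragment_sequence:
        return "correct"
    return "incorrect"


def compute_metrics(counts: EvalCounts) -> MetricSet:
    """Accuracy, precision, recall and F1 from merge counts (F1 = 0 when no TP)."""
    if counts.total == 0:
        raise ValueError("no input pairs to evaluate")
    tp = counts.correct
    fp = counts.merges - counts.correct
    fn = counts.total - counts.merges
    accuracy = tp / counts.total
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if tp > 0
        else 0.0
    )
    return MetricSet(accuracy, precision, recall, f1)


def percent_change(a: int, b: int) -> float:
    """Percentage change from count a to count b: 100*(b - a)/a."""
    if a == 0:
        raise ValueError("baseline count must be positive")
    return 100.0 * (b - a) / a


def evaluate_merged_reads(
    merged: Iterable[SequencingRead],
    truth: Mapping[str, TruthRecord],
    total: int,
) -> EvalCounts:
    """Score a merged-read stream against a truth table keyed by pair id."""
    merges = 0
    correct = 0
    for read in merged:
        key = mate_core(read.identifier)
        if key not in truth:
            raise KeyError(f"no truth record for merged read {read.identifier!r}")
        merges += 1
        if read.sequence == truth[key].fragment_sequence:
            correct += 1
    return EvalCounts(total=total, merges=merges, correct=correct)
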