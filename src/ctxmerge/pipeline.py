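"""End-to-end merging pipeline.

Two streaming passes over the paired input: pass A builds the k-mer count
table from all preprocessed reads (forward reads and reverse-complemented
reverse reads pooled), because every context lookup needs the complete
table; pass B merges each pair independently — find the best overlap, give
up above the mismatch-ratio threshold, resolve remaining mismatches by
quality then by context voting, and emit the virtually elongated read.

Merging different pairs is embarrassingly parallel; the optional thread
pool maps over pair batches and reassembles results in input order, so the
output is byte-identical whatever the worker count.
"""

from __future__ import annotations

import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .fastq_io import (
    ReadPair,
    SequencingRead,
    encode_quality,
    read_paired_fastq,
    reverse_complement_read,
)
from .kmer import KmerTable, build_kmer_table
from .overlap import OverlapStatus, apply_giveup, find_best_overlap
from .resolve import MergeParams, context_pass, quality_pass

__all__ = ["MergeOutcome", "RunSummary", "merge_pair", "run"]

_BATCH = 2048


@dataclass
class MergeOutcome:
    """Per-pair result: the merged read, or the unmerged pair with a reason."""

    pair_id: str
    status: str  # merged | abandoned_mismatch_ratio | no_valid_offset
    merged: SequencingRead | None = None
    offset: int | None = None
    overlap_length: int | None = None

    @property
    def is_merged(self) -> bool:
        return self.status == "merged"


@dataclass
class RunSummary:
    total_pairs: int = 0
    merged_count: int = 0
    abandoned_count: int = 0
    no_valid_offset_count: int = 0
    elapsed_seconds: float = 0.0
    params: MergeParams = field(default_factory=MergeParams)


def merge_pair(pair: ReadPair, table: KmerTable, params: MergeParams) -> MergeOutcome:
    """Merge one pair against a table built from the same input population.

    The merged read Z takes positions 1..b-1 from X and positions b..end
    from Y (with Y's post-resolution qualities over the overlap); its length
    is b - 1 + len(Y).  Failures are statuses, never exceptions.
    """
    x_read = pair.forward
    y_read = reverse_complement_read(pair.reverse)
    pair_id = x_read.identifier

    result = apply_giveup(
        find_best_overlap(x_read.sequence, y_read.sequence, params.omega),
        params.gamma,
    )
    if result.status == OverlapStatus.NO_VALID_OFFSET:
        return MergeOutcome(pair_id, OverlapStatus.NO_VALID_OFFSET)
    if result.status == OverlapStatus.ABANDONED:
        return MergeOutcome(
            pair_id,
            OverlapStatus.ABANDONED,
            offset=result.offset,
            overlap_length=result.overlap_length,
        )

    b = result.offset
    x = list(x_read.sequence)
    q_x = list(x_read.qualities)
    y = list(y_read.sequence)
    q_y = list(y_read.qualities)
    quality_pass(x, q_x, y, q_y, b, params.delta)
    context_pass(x, q_x, y, q_y, b, table, params)

    merged_seq = "".join(x[: b - 1]) + "".join(y)
    merged_qual = q_x[: b - 1] + q_y
    merged = SequencingRead(pair_id, merged_seq, merged_qual)
    return MergeOutcome(
        pair_id,
        "merged",
        merged=merged,
        offset=b,
        overlap_length=result.overlap_length,
    )


def merge_pairs(
    pairs: Iterable[ReadPair],
    table: KmerTable,
    params: MergeParams,
    threads: int = 1,
) -> Iterator[tuple[ReadPair, MergeOutcome]]:
    """Merge a pair stream, preserving input order regardless of thread count."""
    if threads <= 1:
        for pair in pairs:
            yield pair, merge_pair(pair, table, params)
        return
    with ThreadPoolExecutor(max_workers=threads) as pool:
        batch: list[ReadPair] = []
        for pair in pairs:
            batch.append(pair)
            if len(batch) >= _BATCH:
                for p, out in zip(
                    batch, pool.map(lambda q: merge_pair(q, table, params), batch)
                ):
                    yield p, out
                batch = []
        for p, out in zip(
            batch, pool.map(lambda q: merge_pair(q, table, params), batch)
        ):
            yield p, out


def run(
    forward_path: str,
    reverse_path: str,
    out_prefix: str,
    params: MergeParams | None = None,
    threads: int = 1,
    phred_offset: int = 33,
    strict_pairing: bool = False,
) -> RunSummary:
    """Run the full pipeline; writes merged/unmerged FASTQ files and a log.

    Outputs: ``PREFIX.merged.fastq``, ``PREFIX.unmerged_1.fastq`` and
    ``PREFIX.unmerged_2.fastq`` (original orientation), ``PREFIX.log``.
    Output record order equals input order.
    """
    params = params or MergeParams()
    start = time.monotonic()

    def preprocessed() -> Iterator[str]:
        for pair in read_paired_fastq(
            forward_path, reverse_path, phred_offset, strict_pairing
        ):
            yield pair.forward.sequence
            yield reverse_complement_read(pair.reverse).sequence

    table = build_kmer_table(preprocessed(), params.k)

    summary = RunSummary(params=params)
    merged_path = f"{out_prefix}.merged.fastq"
    un1_path = f"{out_prefix}.unmerged_1.fastq"
    un2_path = f"{out_prefix}.unmerged_2.fastq"
    with open(merged_path, "w") as mh, open(un1_path, "w") as u1, open(
        un2_path, "w"
    ) as u2:
        pair_stream = read_paired_fastq(
            forward_path, reverse_path, phred_offset, strict_pairing
        )
        for pair, outcome in merge_pairs(pair_stream, table, params, threads):
            summary.total_pairs += 1
            if outcome.is_merged:
                summary.merged_count += 1
                assert outcome.merged is not None
                _write_record(mh, outcome.merged, phred_offset)
            elif outcome.status == OverlapStatus.ABANDONED:
                summary.abandoned_count += 1
            else:
                summary.no_valid_offset_count += 1
            if not outcome.is_merged:
                _write_record(u1, pair.forward, phred_offset)
                _write_record(u2, pair.reverse, phred_offset)
    summary.elapsed_seconds = time.monotonic() - start

    with open(f"{out_prefix}.log", "w") as log:
        p = params
        log.write(
            f"k={p.k} omega={p.omega} gamma={p.gamma} delta={p.delta} "
            f"quality_weighted_vote={p.quality_weighted_vote} threads={threads}\n"
            f"total_pairs={summary.total_pairs}\n"
            f"merged={summary.merged_count}\n"
            f"abandoned_mismatch_ratio={summary.abandoned_count}\n"
            f"no_valid_offset={summary.no_valid_offset_count}\n"
            f"elapsed_seconds={summary.elapsed_seconds:.3f}\n"
        )
    return summary


def _write_record(handle, read: SequencingRead, offset: int) -> None:
    qual = "".join(encode_quality(q, offset) for q in read.qualities)
    handle.write(f"@{read.identifier}\n{read.sequence}\n+\n{qual}\n")
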