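"""Synthetic paired-end amplicon read simulator with known truth.

Emulates the high-coverage amplicon regime the merger targets: many short
fragments drawn from few reference sequences, read from both ends so the
mates overlap, with a substitution error rate that rises linearly from the
5' to the 3' end of each read — the characteristic quality degradation of
Illumina-style sequencers.  Each base's Phred quality is derived from its
local error rate (Q = -10*log10 p), optionally jittered, so qualities and
errors are mutually consistent.  Errors are substitutions only.

Two named regimes are provided: ``harsh`` (0.001 -> 0.05 per-base
substitution rate, a high-error run) and ``mild`` (0.0005 -> 0.01).
Everything is reproducible from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fastq_io import SequencingRead, write_fastq

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "PRESETS",
    "simulate_references",
    "simulate_pairs",
    "write_truth_table",
    "read_truth_table",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

QUALITY_FLOOR = 2
QUALITY_CEIL = 41

# (error_rate_start, error_rate_end) per-base substitution probabilities
PRESETS: dict[str, tuple[float, float]] = {
    "harsh": (0.001, 0.05),
    "mild": (0.0005, 0.01),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated run.

    Defaults emulate a high-error amplicon run: 100 bp reads from 160-190 bp
    fragments of 23 references (overlaps of 10-40 bp), substitution rate
    rising linearly from 0.001 at the 5' end to 0.05 at the 3' end.
    """

    n_pairs: int = 10_000
    read_length: int = 100
    fragment_length_range: tuple[int, int] = (160, 190)
    n_references: int = 23
    reference_length: int = 1500
    error_rate_start: float = 0.001
    error_rate_end: float = 0.05
    quality_jitter: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.fragment_length_range
        if not self.read_length <= lo <= hi:
            raise ValueError("need read_length <= fragment min <= fragment max")
        if hi >= 2 * self.read_length:
            raise ValueError("max fragment must be < 2*read_length (mates must overlap)")
        for rate in (self.error_rate_start, self.error_rate_end):
            if not 0.0 <= rate <= 0.75:
                raise ValueError("error rates must be in [0, 0.75]")
        if self.reference_length < hi:
            raise ValueError("references must be at least as long as the max fragment")
        if self.n_pairs < 0 or self.n_references < 1:
            raise ValueError("n_pairs >= 0 and n_references >= 1 required")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one pair; true overlap offset b = m - n + 1."""

    pair_id: str
    reference_id: str
    fragment_start: int  # 1-based in the reference
    fragment_length: int
    fragment_sequence: str


def simulate_references(
    n_references: int, length: int, seed: int
) -> list[tuple[str, str]]:
    """Uniform-random A/C/G/T reference sequences as (id, sequence) tuples."""
    rng = np.random.default_rng(seed)
    refs = []
    for r in range(n_references):
        seq = rng.choice(_BASES, size=length).tobytes().decode("ascii")
        refs.append((f"ref_{r:03d}", seq))
    return refs


def _error_profile(n: int, start: float, end: float) -> np.ndarray:
    """Per-position substitution probability, linear from 5' start to 3' end."""
    if n == 1:
        return np.array([start])
    return start + (end - start) * np.arange(n) / (n - 1)


def _qualities(profile: np.ndarray, jitter: int, rng: np.random.Generator) -> np.ndarray:
    with np.errstate(divide="ignore"):
        q = np.where(
            profile > 0,
            np.rint(-10.0 * np.log10(np.maximum(profile, 1e-30))),
            QUALITY_CEIL,
        )
    if jitter > 0:
        q = q + rng.integers(-jitter, jitter + 1, size=len(profile))
    return np.clip(q, QUALITY_FLOOR, QUALITY_CEIL).astype(int)


def _corrupt(
    sequence: str, profile: np.ndarray, rng: np.random.Generator
) -> str:
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < profile
    if hit.any():
        idx = np.nonzero(hit)[0]
        for i in idx:
            choices = _BASES[_BASES != arr[i]]
            arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def simulate_pairs(
    references: Sequence[tuple[str, str]], config: SimulationConfig
) -> tuple[list[SequencingRead], list[SequencingRead], list[TruthRecord]]:
    """Draw fragments and sequence both ends with position-dependent errors.

    The forward read is the fragment prefix of length n; the raw reverse
    read is the reverse complement of the fragment suffix of length n.
    Substitutions hit each position independently with the interpolated
    local rate; erroneous bases are replaced uniformly among the three
    alternatives.  Identical config and seed give identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.read_length
    lo, hi = config.fragment_length_range
    profile = _error_profile(n, config.error_rate_start, config.error_rate_end)

    forward: list[SequencingRead] = []
    reverse: list[SequencingRead] = []
    truth: list[TruthRecord] = []
    for p in range(config.n_pairs):
        ref_id, ref_seq = references[int(rng.integers(len(references)))]
        m = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, len(ref_seq) - m + 1))
        fragment = ref_seq[start : start + m]

        fwd_true = fragment[:n]
        rev_true = fragment[m - n :].translate(_COMPLEMENT)[::-1]

        pair_id = f"pair_{p:07d}"
        fwd_seq = _corrupt(fwd_true, profile, rng)
        fwd_q = _qualities(profile, config.quality_jitter, rng)
        rev_seq = _corrupt(rev_true, profile, rng)
        rev_q = _qualities(profile, config.quality_jitter, rng)
        forward.append(SequencingRead(pair_id + "/1", fwd_seq, fwd_q.tolist()))
        reverse.append(SequencingRead(pair_id + "/2", rev_seq, rev_q.tolist()))
        truth.append(TruthRecord(pair_id + "/1", ref_id, start + 1, m, fragment))
    return forward, reverse, truth


TRUTH_HEADER = "pair_id\treference_id\tfragment_start\tfragment_length\tfragment_sequence"


def write_truth_table(records: Sequence[TruthRecord], path: str) -> None:
    with open(path, "w") as handle:
        handle.write(TRUTH_HEADER + "\n")
        for r in records:
            handle.write(
                f"{r.pair_id}\t{r.reference_id}\t{r.fragment_start}\t"
                f"{r.fragment_length}\t{r.fragment_sequence}\n"
            )


def read_truth_table(path: str) -> dict[str, TruthRecord]:
    """Load truth keyed by pair id (mate suffix stripped)."""
    from .fastq_io import mate_core

    out: dict[str, TruthRecord] = {}
    with open(path) as handle:
        header = handle.readline()
        if header.strip() != TRUTH_HEADER.replace("\t", "\t").strip():
            raise ValueError(f"{path}: unexpected truth-table header")
        for line in handle:
            pid, ref, start, length, seq = line.rstrip("\n").split("\t")
            rec = TruthRecord(pid, ref, int(start), int(length), seq)
            out[mate_core(pid)] = rec
    return out


def write_reference_fasta(references: Sequence[tuple[str, str]], path: str) -> None:
    with open(path, "w") as handle:
        for ref_id, seq in references:
            handle.write(f">{ref_id}\n")
            for i in range(0, len(seq), 70):
                handle.write(seq[i : i + 70] + "\n")


def simulate_to_files(config: SimulationConfig, out_prefix: str) -> int:
    """Simulate and write references, paired FASTQ and the truth TSV."""
    refs = simulate_references(
        config.n_references, config.reference_length, config.seed
    )
    fwd, rev, truth = simulate_pairs(refs, config)
    write_reference_fasta(refs, f"{out_prefix}.refs.fasta")
    write_fastq(fwd, f"{out_prefix}.1.fastq")
    write_fastq(rev, f"{out_prefix}.2.fastq")
    write_truth_table(truth, f"{out_prefix}.truth.tsv")
    return len(truth)
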