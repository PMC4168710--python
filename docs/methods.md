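# Methods

## The merging model

A paired-end sequencer reads a DNA fragment S = ⟨s₁…s_m⟩ from both ends,
producing a forward read X and a reverse read W, each of length n, with
per-base Phred qualities (Q = −10·log₁₀ p, p the probability the call is
wrong). When m < 2n the two reads overlap, and merging them yields a
virtually elongated read covering the whole fragment. The package assumes
substitution-only errors (the dominant error type on Illumina-style
platforms) and an error rate that grows toward the 3′ end of each read, so
the overlap — formed by the two 3′ ends — is the noisiest part of both
reads.

The pipeline has five steps:

1. **Preprocessing.** W is reverse-complemented into Y (qualities reversed
   alongside), so X and Y represent the same strand: with no errors,
   yᵢ = s_{m−n+i}.
2. **k-mer table.** One exact count table T_k over all preprocessed reads
   (X's and Y's pooled — after preprocessing the two mates are effectively
   replicate observations of the fragment strand). Counting is
   non-canonical; windows containing N are not counted and N-containing
   queries return 0.
3. **Overlap detection.** Y is slid against X; for each candidate start
   offset b ∈ [1, n−ω+1] the mismatch ratio (mismatches / overlap length)
   is computed, and the strictly lowest ratio wins. Strict improvement
   keeps the smallest b, i.e. the longest overlap, on ties. If the best
   ratio exceeds the give-up threshold γ the pair is left unmerged.
4. **Mismatch resolution**, two left-to-right passes over the overlap:
   - *Quality pass:* a mismatch with |Q_X(i) − Q_Y(i′)| > δ is resolved in
     favour of the higher-quality base. One-sided N is always overwritten
     by the informative base; double-N positions stay N.
   - *Context pass:* each remaining mismatch is put to a vote over up to k
     progressively shifted k-mer windows C_j covering it,
     j = 1…k. Window j compares T_k[X(i−k+j : i+j−1)] against
     T_k[Y(i′−k+j : i′+j−1)]; the side with the larger count gets the
     vote (equal counts: no vote). The count ratio approximates the
     posterior odds P{X(i) | C_j} / P{Y(i′) | C_j} under the assumption
     that both mates are a priori equally reliable. The final call is a
     linear opinion pool: the forward base wins only on a strict majority;
     ties and the empty vote set go to the reverse base. Windows
     underrunning the left end of either read are skipped; the scan stops
     at a window overrunning the right end of either read or reaching an
     uncorrected downstream mismatch (its bases cannot yet be trusted —
     everything left of the current position has already been resolved).
   - In both passes the winner's base **and quality** replace the loser's,
     so later windows extend over corrected bases.
5. **Merge.** Z takes positions 1…b−1 from X and positions b…b−1+n from Y;
   len(Z) = b − 1 + len(Y) (= m for equal-length error-free reads).
   Qualities of untouched positions are unchanged, which over the overlap
   means Y's (post-resolution) qualities survive — the pseudocode-faithful
   reading; taking the max of the two scores would be a defensible
   alternative.

## Parameters

| parameter | default | meaning |
|---|---|---|
| k  | 17  | context k-mer size (bp); capped at 31 |
| ω  | 10  | minimum overlap length (bp) |
| γ  | 0.5 | give-up mismatch-ratio threshold |
| δ  | 19  | Phred difference above which qualities alone decide |
| quality_weighted_vote | off | scale window counts by each base's error probability 10^(−Q/10) before comparing |

The quality-weighted variant implements the weighting literally as an
error-probability ratio (not a correctness-probability ratio); it is an
ablation flag, off by default, and measurably changes very few decisions —
only those whose count ratio falls inside the quality ratio.

## Design choices where the design was open

- **N in the mismatch ratio:** positions with N on either side are excluded
  from the mismatch count but included in the overlap length. The
  denominator is purely positional; an indecisive call is not evidence of
  disagreement.
- **Boundary checks on both reads:** the context-window boundary rules are
  applied to X's *and* Y's indices (Y's window can underrun even when X's
  is valid); indexing outside a read is meaningless.
- **Ties:** equal-count windows cast no vote; a tied or empty poll goes to
  the reverse base. No randomisation anywhere — the whole pipeline is
  deterministic, and the threaded path maps ordered batches so output is
  byte-identical for any worker count.
- **Unequal read lengths** are supported by generalising the index
  arithmetic (candidate offsets [1, len(X)−ω+1], overlap length
  min(len(X)−b+1, len(Y))); the formulas degenerate to the equal-length
  case.
- **Non-canonical counting:** after preprocessing both mates represent the
  same strand, which is the point of pooling them into one table;
  collapsing a k-mer with its reverse complement would mix in the opposite
  strand's context.

## The simulator

The generator emulates high-coverage amplicon sequencing: uniform-random
references (default 23 × 1500 bp), fragments of uniform length in
[160, 190] bp cut at uniform positions, 100 bp reads from both ends (true
overlap b = m − n + 1, overlap lengths 10–40 bp), substitution errors drawn
independently per position with a probability interpolated linearly from
the 5′ rate to the 3′ rate, and qualities set to round(−10·log₁₀ p_local)
± an integer jitter (default ±2), clipped to [2, 41]. Two presets:
**harsh** 0.001 → 0.05 (a high-error run) and **mild** 0.0005 → 0.01. The
3′ rates were fixed once as round numbers spanning the regimes of interest;
the harsh profile averages ~2.5 errors per 100 bp read, concentrated where
the overlap lies.

What it does **not** emulate: indels, chimeric fragments, PCR duplicates,
quality-model miscalibration (simulated qualities are consistent with the
true local error rate by construction), non-uniform fragment position or
abundance, and real 16S reference structure. Passing tests on this
generator therefore demonstrate the algorithm's mechanics and its error-free
limit, not field performance on real libraries.

## Evaluation

Against simulation truth, a merged read is **correct** only if it is
identical — length and bases — to its fragment. With TP = correct merges,
FP = incorrect merges, FN = unmerged pairs: accuracy = TP/total,
precision = TP/(TP+FP), recall = TP/(TP+FN), F1 the harmonic mean (0 when
TP = 0). This scoring reproduces, to the printed 3 decimal places, every
row of the published benchmark table it was reconstructed from, given that
row's raw counts.

The exact-identity criterion is deliberately strict: the merger corrects
only the overlap, so any error in the non-overlap portions makes a merge
"incorrect" even when the overlap was resolved perfectly. Under the harsh
profile most pairs carry such errors, so whole-read accuracy is low
(≈0.05) while the overlap itself is fully and correctly resolved at the
true offset in ≈73% of pairs; the error-free limit merges 100% of pairs
exactly. Both numbers are recomputed, not quoted, by
`scripts/acceptance.py`.

## Problem sizes and numerics

Test and acceptance runs use 10⁴–2×10⁴ simulated pairs (10⁵ for the
error-profile calibration check), sizes at which the exact in-memory k-mer
dictionary and the vectorised per-offset overlap scan finish in seconds;
the overlap scan is cross-checked exhaustively against a pure-Python brute
force on short reads. Parameter-sweep tests assert trends (monotonicity,
plateaus, spreads) with small slacks rather than absolute accuracies, since
sweep differences on 10⁴ pairs sit near the binomial noise floor.

## Known limitations

- No indel handling: an indel inside the overlap shifts the frame and the
  pair will typically be abandoned or merged incorrectly.
- Non-overlapping pairs (m ≥ 2n) and gapped inserts are out of scope; the
  overlap search will still report its best (spurious) offset and the
  give-up threshold is the only guard.
- A short spurious perfect overlap can beat the true offset when the true
  overlap contains errors (ratio 0 < any positive ratio); lowering ω below
  ~10 increases that risk.
- The k-mer table holds exact counts in memory (fine up to a few million
  reads; ~tens of bytes per distinct k-mer).
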