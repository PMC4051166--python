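# Methods

This note documents the models, conventions and numerical choices behind
`mapbench`, and what its synthetic benchmarks do and do not demonstrate
about real data.

## Read simulation model

Reads emulate single-end ion-semiconductor-style sequencing:

* **Length.** Drawn per read from Normal(`mean_length`,
  `sd_fraction · mean_length`), rounded to the nearest integer and clamped
  to ≥ 20 bases (degenerate alignments below that length are not useful;
  clamping is logged through the run statistics). Defaults: mean 200,
  SD 10% of the mean.
* **Origin.** The sampled length is the *reference window span*: start
  positions are uniform over all valid 1-based starts, contigs weighted by
  their number of valid windows; strand is uniform over {+,−} (a
  `both_strands=False` switch restricts to forward). Windows with more than
  10% `N` are rejected and redrawn (50 tries, then a configuration error
  reporting the N-density).
* **Errors.** Per window position, one uniform draw decides deletion
  (probability `del_rate`) or substitution (`sub_rate`, new base uniform
  over the three alternatives — never the original); an independent draw
  inserts a uniform base before each position with probability `ins_rate`.
  Defaults 0.5% insertions / 1% deletions / 0.5% substitutions, the
  indel-dominant profile of the platform family; the 9-point
  `DATASET_GRID` spans total error rates 0–4%.
* **Placement modes.** `uniform` (default); `ramp3prime` scales all rates
  linearly from 0.5× at the read start to 1.5× at the end (3′ quality
  decay); `homopolymer` doubles the indel mass inside runs of length ≥ 3.
  Both reweightings are renormalized to mean 1 per window so the expected
  genome-wide rates equal the configured rates.
* **Random reads.** `random_fraction` (default 5%) of reads are i.i.d.
  uniform bases — unmappable by construction — interleaved at seeded-random
  positions; they probe false-positive mapping and are true negatives under
  the default scoring policy.
* **Qualities.** Constant quality character (default `I`); the evaluation
  never uses base qualities.

Because emitted length = span − deletions + insertions, the mean emitted
read length at the default rates is ≈ 0.995 × the configured mean (199 for
200); the standard 50,000 × 200 dataset over a 250 kb reference therefore
covers ≈ 39.8×, matching the nominal 40× design to within half a percent.

## Canonical ground truth

Injected edits are not directly usable as truth: compensation (delete a
base, reinsert the same base; adjacent deletion/insertion pairs collapsing
to a substitution; indels at the window boundary merely shortening the
covered span) makes the *observable* edit count smaller. Truth is therefore
defined by a canonical alignment of the read against its source window:

* unit costs, global on the read, free end gaps on the reference side;
* among minimal-cost alignments, the one with the fewest substitutions
  (equivalently most matches) — so a cost-equal insertion/deletion pair is
  never arbitrarily recounted as substitutions;
* remaining ties broken toward the leftmost end column and leftmost gaps,
  mirroring VCF left-alignment.

The DP is O(read × window) and JIT-compiled (numba), with a pure-Python
fallback. The truth table stores the canonical counts and the 1-based
forward-strand coordinates of the reference bases actually covered; for
reverse-strand reads the alignment is computed in read space against the
reverse-complemented window and flipped back.

**Expected compensation deficit.** Edit–edit interactions shrink the
canonical indel count below the raw injected count by O(rate²):
a deletion with an insertion in an alignment-adjacent slot (probability
≈ 2·ins·del per base, amplified ~2–3× by re-synchronisation through
chance base matches in random DNA) converts two indels into at most one
substitution, and a deletion of the first/last covered base
(≈ 2·del/mean_length per base) becomes free. At the maximum grid setting
(1% ins + 2% del) this predicts a deficit of roughly 0.1–0.15 percentage
points on the ≈ 3% indel rate — a few percent of the configured rate. The
simulator tallies raw and canonical counts per run and logs the realized
deficit; tests bound it at 5% of the configured indel rate and verify the
*raw* counts against exact binomial expectations.

## Mapping evaluation

The correctness rule and shift mechanics are described in the README. The
choices that were genuinely open:

* `max_shift` defaults to 5 per end: it bounds the sum of the positional
  offset (missing deletions) and clipped bases (missing insertions)
  absorbed at each alignment extremity. Clipping beyond the budget
  disqualifies a hit — the rule demands a full-length read alignment.
* A hit on the opposite strand is incorrect (the stricter reading).
* Random reads: by default correctly rejected random reads leave the
  formulas as true negatives and mapped random reads are false positives
  (`exclude_random`); a `literal` policy instead counts unmapped random
  reads as false negatives, which caps recall at 1 − random_fraction. Both
  are exposed because the published formulas are ambiguous on this point.
* Reads absent from the SAM are unmapped; all hits of a read (secondary and
  supplementary included) are eligible to satisfy the rule.

`build_truth_sam` reconstructs the SAM an ideal mapper would emit from a
truth table (synthetic CIGAR `1M {ins}I 1M {del}D kM` reproducing the
canonical counts, NM tag set accordingly): it is the round-trip oracle for
the whole chain (simulate → SAM → parse → classify must give precision =
recall = F = 1) and the baseline for corruption experiments.

Repeat recovery: a read is repeat-located iff its truth start lies inside a
repeat-copy interval (start-within, which is read-length-invariant); for
each such read the evaluator counts distinct copies with at least one hit
at the equivalent within-copy offset ± `max_shift` and reports the 0..n
class histogram in percent.

## Benchmark genome generators

* `mutate_genome` introduces exactly `round(rate · length)` mutations per
  contig (deterministic truth-table size), positions sampled uniformly
  without replacement with pairwise gaps ≥ 2 so anchored edits never
  overlap; each is a substitution with probability `sub_fraction` (default
  0.9), else a 1 bp insertion or deletion (equiprobable; indel length is
  configurable but defaults to 1). Records are anchored (insertion: 1-base
  ref / 2-base alt) in original-genome coordinates, and applying them
  reproduces the mutated genome byte-exactly.
* `build_repeat_genome` draws a uniform-random background and a master
  repeat, then plants `n_copies` copies at evenly spaced, non-adjacent
  positions, each independently substituted at the divergence rate
  (substitutions only, keeping copies colinear so "equivalent position
  within a copy" is well defined). Defaults: 250 kb, five copies of 500 bp,
  3% divergence. The divergence-vs-read-error ambiguity is resolved as copy
  divergence; setting `--divergence 0` recovers the identical-copy reading.

## Variant-discovery scoring

Truth mutations are original→mutated edits in original coordinates; a
caller mapping sample reads against the *mutated* reference reports each
one in mirror orientation (mutated coordinates, ref/alt swapped, insertion
appearing as deletion). `match_and_score` therefore lifts each call back
through the cumulative indel offset of preceding mutations, swaps its
alleles, left-normalizes both sides against the original reference and
requires identical kind, position and alleles; each call matches at most
one truth record. "Equivalent position" is thus realized as equality after
left-normalization. Calls whose lifted ref allele contradicts the original
reference are false positives (IM) with a warning; if more than half the
calls fail that check the run aborts with a coordinate-system error.
The printed recall denominator CM+IM+NM is used as-is (it differs from the
conventional CM/(CM+NM); `--conventional-recall` switches). VCF input is
filtered at depth ≥ 10 and alternate frequency ≥ 80% (both inclusive)
before scoring.

## What the synthetic benchmarks do not show

The generators emulate read-scale error statistics, not sequencing physics:
no flow-space signal model, no quality-value correlation with error
probability, no paired ends, no structural variation, no GC or coverage
bias, and backgrounds are i.i.d. uniform DNA (real genomes have skewed
composition and genuine repeat families). Passing the perfect-SAM and
truth-VCF round trips certifies the *accounting chain* — truth encoding,
parsing, canonicalization, classification, scoring — not any mapper's
behaviour on real libraries; conclusions about real data require running
real mappers on these benchmarks.

## Problem sizes and determinism

Unit tests run at reduced scale (50 kb references, 10³–10⁴ read datasets,
≥ 10⁶ simulated bases for rate checks); the acceptance script and the
full-scale acceptance tests use the benchmark's native design — 250 kb
reference, 50,000 reads, 2,500 mutations — and complete in about a minute
each on one CPU. All stochastic steps flow from a single
`numpy.random.default_rng` seed per run; a fixed seed reproduces FASTQ,
TSV and FASTA outputs byte-identically, and the CLI records the seed (drawn
from OS entropy when omitted) in its run manifest.
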