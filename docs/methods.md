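# Methods

## Problem and model

`lcsclust` partitions a set Q of DNA reads into clusters of mutually similar
sequences by greedy incremental clustering: reads are processed in a fixed
order, each read either joins the cluster of an existing representative to
which its alignment identity reaches a threshold s, or founds a new cluster
and becomes its immutable representative. Identity of a pair with lengths
m ≥ n is defined as the number of matched columns in a score-optimal
affine-gap alignment divided by n, the shorter length. Because
representatives never change, the result depends on the processing order;
this is the price of comparing each read against representatives only
(roughly O(N·|R|) pairs rather than O(N²)).

The engine's cost is dominated by alignment, so two filters prune the
candidate set first.

**Short-word filter.** A pair with high identity must share contiguous
k-mers. Representatives register every k-th k-mer (plus a tail word when the
stride does not reach the final window, so the last bases stay visible) in a
direct-address table of 4^k buckets; queries enumerate all their k-mers. A
pair survives when at least t query positions carry a word registered for
that representative. Registering only every k-th word cuts table memory and
lookup work to about 1/k, in exchange for a low t whose extra false
positives the next stage removes. k-mers containing N have no radix-4 code
and are skipped on both sides; multiplicity on the representative side is
ignored (counting is per query position), which keeps the count cheap and
monotone in t.

**LCS filter.** For shorter length n, LLCS(X, Y)/n ≥ identity(X, Y), since
the LCS is exactly the match-maximizing alignment and the identity numerator
comes from a (generally different) score-maximizing alignment. Pairs whose
ratio falls below s are rejected before alignment; pairs with identity ≥ s
can never be rejected — the filter reuses s itself and adds no tuning knob.
The bound is loose for long sequences (gappy alignments can accumulate
matches), so its rejection power is strongest for short reads.

## Bit-parallel LLCS kernel

LLCS is computed with a Hyyrö-family bit-vector algorithm. `compute_pm`
builds one m-bit position mask per symbol of {A,C,G,T} over the indexed
sequence X (LSB = position 0; N positions appear in no mask), in
O(σ⌈m/w⌉ + m). The scan of Y is, per character,

    U ← V ∧ PM[y_j]
    V ← (V + U) ∨ (V − U)

with V initialized to all ones; LLCS is the number of cleared bits among the
low m bits of the final V, and the whole scan costs O(σ⌈m/w⌉·n). Masks are
stored as ⌈m/w⌉ blocks of w bits (w configurable, default 64) and the
addition's carries are chained across adjacent blocks explicitly. Two
numerical facts keep the blocked form simple: U is bitwise a subset of V, so
V − U never borrows between blocks and reduces to V ⊕ U per block; and
carries that overflow past bit m only ever move upward, so the garbage bits
above m in the top block cannot corrupt the counted region. The textbook
O(mn) dynamic programme (`llcs_dp`, with the left-neighbour dependency
folded into a prefix maximum so rows are numpy-vectorized) is kept as the
oracle; the test suite checks kernel/oracle equality on exhaustive short
pairs (against an independent subsequence-enumeration brute force as well)
and on random pairs spanning multiple blocks at several widths.

X is always the cluster representative, so its masks are built once, cached,
and reused across all queries that reach the LCS stage.

## Alignment

The final arbiter is a global affine-gap (Gotoh three-state) alignment,
computed by Biopython's `PairwiseAligner`. A gap of length L costs
gap_open + (L−1)·gap_extend. Defaults: match +2, mismatch −2, gap_open −6,
gap_extend −1, end gaps free. End-gaps-free (semi-global) is the default
because reads of unequal length should not pay for overhangs, which pairs
naturally with the shorter-length denominator; full global scoring is a
configuration switch. N aligned against anything, including another N,
scores and counts as a mismatch, so an ambiguous base can never raise
identity. Because co-optimal alignments can disagree on their match count,
the pair is aligned in a canonical orientation (longer sequence as target,
ties broken lexicographically) and matches are read from the first
deterministic traceback — making identity a well-defined, symmetric function
of the pair. Match counts of a score-optimal alignment never exceed LLCS,
which is what makes the filter bound safe.

No banding is applied: the candidate volume reaching the aligner is already
pruned by two filters, and full DP keeps the optimum exact.

## Clustering parameters

| parameter | default | meaning |
|---|---|---|
| s | 0.9 | identity threshold in (0,1]; inclusive boundary |
| k | 9 | word length, bases; direct-address table needs k ≤ 12 |
| t | auto | common-word threshold; auto = 1 for reads ≤ 200 b, 4 above, resolved from the median input length |
| ordering | length_desc | processing order; `input` preserves file order |
| assignment | first | join earliest-created accepting cluster; `best` takes the highest identity |
| w | 64 | LLCS block width, bits |

s = 0.9 with k = 9 is the common operating point for metagenomic
deduplication of 100–400 b reads; t defaults to 1 for short reads because
the strided registration leaves ~L/k words per representative, and to 4 for
longer reads where chance matches grow. Degenerate inputs are handled
without exceptions: reads shorter than k and all-N reads register/enumerate
no words, meet no candidates, and found singleton clusters.

First-hit assignment and length-descending order are deliberate choices
where the procedure itself is underdetermined: first-hit is the fastest
greedy rule and the CD-HIT convention; longer representatives absorb shorter
reads better when representatives are never updated. Both have switches
(`assignment=best`, `ordering=input`) for strict as-given processing.

## Synthetic data generator

`lcsclust.synth` emulates a deduplication workload: n_seeds uniform-random
seed sequences (rejection-sampled until all pairwise identities stay below
1 − min_seed_divergence), each emitted together with reads_per_seed mutated
copies; per-base substitutions (rate 0.03 by default) and indels (0.005,
half insertions, half deletions) are position-independent, so a read's
expected identity to its seed is ≈ 1 − sub_rate − indel_rate, and the
records are deterministically shuffled. Defaults (20 seeds × 10 reads of
150 b, divergence cap 0.2) produce within-family identities ~0.95–0.97
against cross-family identities ≤ 0.8 — a clearly clusterable regime with
known labels.

What the generator does *not* emulate: genomic base composition and repeat
structure (seeds are uniform random), sequencer-specific error profiles
(homopolymer errors, quality decay), chimeras, or paired ends. Passing the
recovery tests therefore demonstrates the correctness of the cascade and
the greedy engine on well-separated families; it does not measure clustering
quality on real reads, where family separation and error structure are less
benign. Note that with a shuffled processing order the founding
representative of a family is itself a mutated copy, so two reads at 3%
divergence from their seed sit at ~6% expected divergence from each other;
occasional reads fall below s = 0.9 against their family's representative
and correctly found extra singletons. Recovery is therefore measured by
adjusted Rand index rather than by an exact cluster count.

## Problem sizes in the tests and acceptance script

The suite verifies the bit-parallel kernel on 10,000 random pairs of lengths
1–320 (five 64-bit blocks) plus 100,000 short pairs, the filter bound on
1,000 pairs at each s ∈ {0.8, 0.9, 0.95}, the aligner against brute-force
enumeration on 10,000 pairs of lengths ≤ 5, ground-truth recovery on the
220-read fixture (ARI ≥ 0.99 at its fixed generator seed), and an
end-to-end 10,000-read run in which the LCS stage rejects a strict subset
of short-word survivors. `scripts/acceptance.py` recomputes the same
quantities at sizes (3,000 kernel pairs, 2,000-read cascade run) chosen to
keep a full from-scratch reproduction in the low minutes on one core; all
of its inputs are generated at run time from `--seed`.

## Known limitations

- Order dependence is inherent to greedy clustering with frozen
  representatives; two orderings can split or merge families near s.
- The LCS bound weakens as reads lengthen, so filter efficiency (and hence
  speed-up) is best for short reads; no gap-aware correction of the bound is
  attempted.
- The word table holds plain Python lists and is never evicted; memory is
  ~1/k of an all-words table but not otherwise capped.
- Identity from one canonical traceback: a different co-optimal alignment
  may have a different match count; only the canonical one is reported.
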