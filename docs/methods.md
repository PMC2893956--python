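# Methods

## The model

After a whole-genome duplication, every ancestral gene exists as a
homeologous pair. Fractionation removes one copy of most pairs over time.
The package models this as a sequence of deletion events on two parallel
gene arrays (the homeologs), with three structural assumptions:

1. **Events delete blocks of whole genes.** An event removes m consecutive
   genes, with m drawn from a *deletion-length mixture* over 1..5 genes.
   The default `BEST_FIT_MIXTURE` is 80% one-gene, 15% two-gene, 5%
   three-gene deletions; `SINGLE_GENE` (100% one-gene) is the null
   mechanism.
2. **The chromosome re-ligates after every deletion.** Event positions are
   uniform over *surviving* genes, so later events can land adjacent to
   earlier deletions and fuse with them. Observed runs are therefore
   *apparent* runs, measured in the original gene order; they are longer
   than single events, which is why a pure single-gene mechanism still
   produces multi-gene runs. Under the single-gene mixture this process is
   exactly uniform sampling of k deleted positions without replacement —
   the identity the enumeration oracles in the test suite exploit.
3. **Mutual exclusion between homeologs.** In the two-copy model, once a
   gene is lost from one homeolog its ortholog on the other homeolog is
   never deleted (losing both copies is assumed lethal and purged by
   selection). Events choose homeolog 1 with probability `bias`
   (0.5 = unbiased).

## Retention codes and reduction

Input regions are strings over `{B,1,2,0,D,N}` (see README). Reduction to
the *essential code* proceeds in a fixed order: drop `D`/`N`/`0`; drop
maximal runs of `1` or `2` strictly longer than 9 genes (such runs are
putative segmental translocations, not deletions — the copy did not die,
it moved); trim both ends to the first/last `B`. Every discarded gene is
logged to stderr with its reason. Reduction is idempotent, and surviving
records keep their original positions so runs can be mapped back.

Because `0`-coded genes are removed before run measurement by default, a
`0` does not split a run of `1`s; the `long_runs_on_raw` flag measures
long runs on the raw string instead, for sensitivity analysis. Tandem
arrays are condensed beforehand (`condense_tandem_arrays`): within a
cluster of same-family genes separated pairwise by at most 3 interrupters,
the leftmost gene keeps its code and the rest are recoded `D`.

## Bias statistics

`binomial_bias_test(a, b)` is the exact one-sided cumulative binomial
probability P(X ≤ min(a, b)) with n = a + b and p = ½. One-sided is a
deliberate choice: it reports ≥ 0.5 for balanced regions (a two-sided test
would report ~1.0 there) and matches the published per-region values. The
symbol-to-homeolog mapping (code `1` = deletion on homeolog 2) is a single
named constant, `DELETION_SYMBOL_FOR_HOMEOLOG`. Ties in the under/over
assignment are flagged and should be excluded from aggregate ratios.

Ks-ratio trimming (`trim_extreme_ks_ratios`) ranks pairs by absolute
log-distance of their over/under Ks ratio from the median ratio and
removes the top `ceil(fraction * n)` (default fraction 0.16); gross
outliers typically reflect misalignments or pseudogene alignments. The
log-distance extremeness metric is this package's choice of how to rank
"most extreme relative to the median".

## Monte Carlo simulators

Each replicate applies the event model above until the target is hit
exactly: the deletion simulator stops at `n_deleted` deleted genes (the
final event is trimmed on overshoot), the two-copy simulator at
`n_retained_target` both-retained genes. Block deletions truncate at the
array end rather than wrapping or resampling. In the two-copy simulator,
multi-gene events span m consecutive genes in the hit copy's ligated
coordinates; genes protected by mutual exclusion are spanned but skipped.

Envelopes summarize per-length replicate run counts by the interpolated
median and nearest-rank 2.5th/97.5th percentiles. Default 1,000
replicates; tests use 30–500 except the small-case oracle comparisons,
which use 30,000 for tight standard errors. Each simulation consumes one
seed; per-replicate streams derive from it via `SeedSequence`, so results
are bit-reproducible. Inner loops are compiled with numba and index
survivors with a Fenwick tree (O(log n) rank→position selection), keeping
a 1,500-gene, 600-deletion replicate at ~0.1 ms.

`compare_to_envelope` flags every run length whose observed count falls
outside the 95% interval; lengths absent from one side count as zero.

## Genetic-algorithm mixture fit

The mixture is encoded as 20 slots, each holding a length 1..5, giving 5%
weight granularity. Fitness of a candidate is
Σ_lengths |median simulated run count − observed run count|, with the
medians from the deletion simulator at the observed (n_genes, n_deleted).
The evolutionary operators are this package's own design (the fit target
and genome encoding are the method; the operators were open): population
50, tournament selection (k = 3), one-point crossover with probability
0.7, per-slot mutation probability 0.05 (uniform reassignment in 1..5),
elitism of 1. Every genome — including the carried-over elite — is
re-evaluated each generation with a fresh generation seed, so a lucky
Monte Carlo draw cannot lock in. Default 500 generations (a scaled-down
budget; recovery experiments at n ≈ 1,500, k ≈ 600 converge well within
it). `FitResult.history` is the running best (non-increasing by
construction); `history_raw` keeps the noisy per-generation elite scores.

## Direct-repeat footprints

Intra-chromosomal recombination between two direct repeats excises the
intervening DNA as a circle and leaves one repeat copy. In a
precursor/product comparison this makes the deletion placement ambiguous:
`product == precursor[:s] + precursor[s+gap:]` holds for a contiguous
range of start offsets s, and the *width of that range equals the length
of the flanking direct repeat*. `infer_deletion_interval` computes the
range from the longest matching prefix and suffix (O(n), no alignment),
verifies the pair is explained by exactly one contiguous deletion, and
reports the repeat. Matching is exact: `N` never matches anything
(including `N`), so unknown bases cannot manufacture repeats — a pair
with `N` in the conserved portion is rejected rather than guessed at.
Sequences are compared as given (deletions are intra-allelic; no
reverse-complement search), and imperfect repeats are out of scope.
`classify_footprint` calls an event a footprint at repeat length ≥ 3 bp,
the lower end of the published 3–24 bp range. Multi-gap genes must be
split into one window per gap (`split_by_anchors`) using caller-supplied
anchor coordinates.

## Synthetic data

`generate_region` runs the same compiled two-copy engine as the retained
simulator (one event engine, so generator and simulator cannot drift
apart) and records the full event log; an assertion replays the log and
must reproduce the emitted code string. Defaults are the study
conditions: 2,943 genes, deletion fraction 0.57 (43% of genes retained as
pairs), bias 0.70 (a 2.33:1 over/under deletion ratio), 80/15/5 length
mixture.

`generate_sequence_pair` plants a repeat R around an insert X between
random flanks A, B: precursor `A+R+X+R+B`, product `A+R+B`. The apparent
repeat would exceed the planted one exactly when the first insert base
equals the first base of B or the last insert base equals the last base
of A; such inserts are rejected (up to 100 resamples), so ground truth is
exact by construction, independent of the detector. Base composition is
uniform A/C/G/T by default with a configurable GC fraction.

What the generator does *not* emulate: inversions and assembly artifacts
(resolved manually in real annotation), transposon landscapes, spatially
heterogeneous deletion rates, gene-importance variation in retention, Ks
evolution, and imperfect direct repeats. Tests passing on synthetic data
therefore validate the statistical machinery and the stated model, not
the annotation pipeline that produces real code strings.

## Numerical choices and degenerate inputs

- Coordinates are 0-based, intervals half-open, everywhere.
- The binomial p-value and all ratios are full precision internally;
  2-decimal rounding happens only in table output.
- A region with no `B` after removal raises (untrimmable) rather than
  returning an empty region; a region with zero deletions yields a bias
  result with absent p-value rather than an error.
- `pool_runs` of an empty list is the empty histogram; pooling mixed run
  kinds is an error.
- Long-run threshold means *strictly greater than* 9 genes: a run of
  exactly 9 survives.
- GA weights always form an exact probability vector in 1/20 increments.

## Problem sizes

Recovery experiments run at n_genes = 1,500 with 600 deletions (single
regions) and 2,943 genes for the genome-scale generator, with GA budgets
of 500 generations, population 24, 12 fitness replicates — sizes at which
repeated fits recover a planted 0.80 one-gene weight within ±0.10.
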