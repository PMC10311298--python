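# Methods

## Model and assumptions

The package indexes the n distinct k-mers of a spectrum-preserving
string set (SPSS): ordered strings over {A,C,G,T}, each of length ≥ k,
jointly containing every k-mer exactly once. Strings are treated
forward-strand only; reverse complements and canonical k-mers are out of
scope by design, as is constructing the SPSS itself from reads or
genomes (that is the job of compacted de Bruijn graph tooling upstream).
The assumption that no string-end k-mer overlaps another string's start
by k−1 symbols affects only SPSS optimality, not index correctness, and
is not validated.

A random minimizer scheme (k, m, seed) orders m-mers by a seeded 64-bit
hash; the minimizer of a k-mer is its smallest m-mer, leftmost on ties.
A super-k-mer is a maximal run of consecutive k-mers sharing one
*occurrence* of a minimizer: the decomposition tracks the minimizer's
absolute start position, so a recurrence of the same m-mer value at a
new position correctly terminates the super-k-mer. Within a super-k-mer,
minimizer positions decrease by exactly one per k-mer, which yields the
implicit rank `p_first − p + 1` and, globally, the locality property
f(x_{i+1}) = f(x_i) + 1.

## Index layouts

Both layouts hash the distinct minimizers with an inner MPHF `fm` and
store per-slot metadata; ambiguous minimizers (those with more than one
super-k-mer; ξ denotes the fraction of k-mers affected) are recorded
with the impossible super-k-mer size 0 and their k-mers delegated to a
fallback MPHF whose codes occupy the tail `[n_unamb..n)` of the
codomain — keeping the main prefix sums independent of ξ. In the
partitioned layout the ambiguous slots are typed right-max, whose lookup
path already reads a size, so the sentinel costs nothing extra.

Codes are 0-based: the lookup expression `L[i] + P[i] − p` with
p ∈ [1..p₁] natively produces `[0..n−1]`, and the convention is kept
throughout. Partition order is left-right-max, left-max, right-max,
non-max; the per-partition k-mer totals (N_lr = w · #LR-slots, and the
final prefix sums of the other three) are what the partition prefixes
add, which is the only reading under which the partitioned lookup is a
bijection. Queries for k-mers outside the indexed spectrum return
arbitrary values, reduced modulo n so the contractual range holds; an
MPHF is not a membership structure and no false-positive guarantee is
implied. Streaming lookup resolves `fm` once per minimizer run and emits
successor codes by the +1 rule; it is elementwise identical to
per-k-mer lookup by construction, also on alien sequences.

Degenerate inputs degrade gracefully: if every minimizer is ambiguous
the index becomes fallback-only and is still minimal perfect; w = 1
makes every super-k-mer a singleton of type left-right-max.

## Storage and space accounting

* `L`, `Ll`, `Lr`, `Ln` (size prefix sums): Elias-Fano, low bits
  `max(0, floor(log2(u/n)))` wide, unary high bits.
* `P`, `Pn` (first-k-mer minimizer positions): fixed-width bit-packed
  integers of `ceil(log2 w)`+1 bits. These arrays are not monotone, so
  fixed-width packing is used instead of Elias-Fano; at w ≤ 64 the cost
  difference is negligible.
* `R` (FL types): two-level wavelet tree, 2 bits/symbol payload.
* Bitvector rank: absolute 64-bit counters every 512 bits (12.5%
  redundancy, 2.25 bits/symbol for the wavelet tree).
* Inner and fallback MPHF: multi-level collision-cascading bitmaps with
  load factor gamma = 2 (~4 bits/key), chosen as the simplest
  expected-linear-time construction meeting the MPHF contract; keys are
  reduced to 64-bit fingerprints, with a deterministic whole-build
  reseed in the (astronomically rare) event of a fingerprint collision
  and an explicit remainder table guaranteeing termination.

`space_bits()` reports the nominal succinct sizes above. The
pure-Python realization additionally keeps derived query caches
(per-word popcounts, decoded Elias-Fano values, a plain symbol array for
vectorized wavelet-tree queries); they are recomputable from the packed
payload, are rebuilt on deserialization, and are not counted or stored.
Serialization is little-endian with magic `LPMH`, a format version, and
length-prefixed sections; truncation and tampering are reported with
byte offsets. Builds are deterministic: identical input and seeds give
byte-identical indexes.

Hashing: m-mers are packed 2 bits/symbol into one 64-bit word
(big-endian within the word) and mixed with a SplitMix64 finalizer;
byte-string keys (fallback k-mers, serialized as ASCII) go through
FNV-1a before the same mix. This fixes the byte encoding that the
serialization format depends on. The packing limits m to ≤ 32, which
covers all recommended configurations (m ≤ 28 even at k = 63).

## Closed forms

With w = k − m + 1 and W = (1 − 1/w)/2:

* expected super-k-mer density d = 2/(w+1), valid for
  m > (3+eps)·log4(w+1) (the scheme warns below that threshold);
  lower-order o(1/w) terms are dropped;
* FL-type probabilities p_lr = W² + 1/w, p_l = p_r = W(1−W), p_n = W²
  (summing to 1; at w = 1 the distribution is degenerate at
  left-right-max);
* unpartitioned space bound n·(2/(w+1))·(log2(4(w+1)²) + b + overhead)
  bits, with b > log2(e) the inner MPHF's bits/key and a single
  user-settable `overhead` constant (default 0.5) standing in for all
  little-o redundancy terms. No analogous closed-form bound is computed
  for the partitioned layout; its advantage is validated empirically
  against the unpartitioned one instead.

**Known bias of the FL-type model.** The probabilities above come from a
Markov-chain model that multiplies the first-k-mer and last-k-mer
position probabilities as if independent. On random sequences the
model's *marginal* relations hold tightly (measured p_lr − p_n agrees
with 1/w to within noise, p_l = p_r, and the boundary probability
(1 + 1/w)/2 is reproduced), but the absolute fractions carry a stable
systematic deviation of about ±0.01 at w = 11 (measured ≈ (0.286,
0.260, 0.259, 0.195) against computed (0.298, 0.248, 0.248, 0.207) on
10⁶ k-mers, consistently across seeds). The deviation shrinks only
slowly with w and exceeds any 4σ statistical band once n_superkmers is
in the 10⁵ range; the corresponding acceptance test documents and
exposes this. The density and ε predictions are unaffected.

## Synthetic data

`synthetic_spss(n_target, k, n_strings, seed)` draws i.i.d. uniform
bases and enforces k-mer distinctness with a seen-set, re-building a
string base-by-base (choosing among the admissible bases in random
order) whenever a collision occurs — rare while 4^k ≫ n_target, which
is warned about otherwise. The output has exactly n_target k-mers,
fragmentation (n_strings − 1)/n_target, and passes full SPSS
validation. It matches the i.i.d. model under which the closed forms
are derived; it does **not** emulate genomic repeats (which inflate the
ambiguous fraction ξ), GC bias, or long-range structure, so passing the
statistical tests here demonstrates agreement with the model, not
performance on any particular genome.

Problem sizes used by the test suite: 21 fixtures from 10 to 10⁵
k-mers across k ∈ {15, 31, 63} for the bijectivity/locality properties,
and a single-string 10⁶-k-mer fixture (k = 31, m = 21) for the
density, ε, FL-census and space-trend measurements — large enough that
the 4σ binomial bands are a fraction of a percent, small enough that
the whole suite runs in well under a minute.

## Numerical and design choices

* 1-based minimizer positions inside k-mers (keeping the rank formulas
  literal), 0-based half-open offsets for super-k-mers inside strings.
* Ties in minimizer hashes break leftmost; `argmin` over the hash
  window realizes this directly.
* Statistical tests use 4σ binomial bands: deterministic, with
  negligible false-failure probability at the sample sizes used.
* Duplicate k-mer detection in validation uses exact 2-bit packed
  integer keys (arbitrary k via Python integers), so no false duplicate
  reports are possible.
* The suggested m per k (CLI guidance table) follows the usual
  log4(input size) rule of thumb for genome-scale data; m is always
  explicit in reproducible runs.

## Limitations

* Forward-strand only; no canonical k-mers.
* m ≤ 32 (single-word packing).
* The recursive multi-level treatment of ambiguous minimizers and
  non-random minimizer orderings (e.g. sampling schemes with lower
  density) are not implemented.
* Throughput is numpy-vectorized but not competitive with native-code
  implementations; the contracts (bijectivity, locality, space
  accounting) are the point, not wall-clock speed.
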