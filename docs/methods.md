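# Methods

## Problem setting

Given `m` labeled samples with `n` numeric features, exhaustive feature
subset selection evaluates a classifier on each of the `2^n − 1` non-empty
feature subsets and selects the arg-min of an internal cross-validation
error. For a distance-based classifier the dominant cost is one `m×m`
distance matrix plus one r×f cross-validation per subset; `eknn` reduces
both.

## Subset order and codec

Signatures are strictly increasing tuples of 1-based feature indices. The
enumeration order is prefix-first lexicographic: `a ⊏ b` iff `a` is a
proper prefix of `b`, or the first differing index of `a` is smaller. The
parent of a signature (its largest index removed) is always visited
earlier, so a depth stack of cumulative matrices along the current parent
path suffices.

Positions (ids) run from 1 (empty set) to `2^n`. Both codec directions are
O(n): at stage `i` the block of signatures whose next index is `i`
occupies positions `[2, 2^(n−i)+1]` relative to the current prefix;
decoding either enters the block (emit `i`, consume one position) or skips
it (`id −= 2^(n−i)`, try `i+1`). Encoding sums the same block spans. The
decoder is iterative, not recursive, so depth is no concern at n = 40+;
ids are kept in 64-bit integers and `n ≤ 62` is enforced. The empty
signature exists in the codec (id 1) but is excluded from evaluation
ranges, which start at id 2.

## Incremental distance matrices

Only *decomposable* (product) distances are supported: the matrix of a
subset is the entrywise sum of per-feature matrices. The registry
therefore accepts per-feature kernels only — squared difference
(`sqeuclidean`, the default) and absolute difference (`manhattan`) are
built in — which makes decomposability structural rather than assumed.
Rooted Minkowski distances are not decomposable and cannot be registered;
monotone transforms of a decomposable distance leave k-NN predictions
unchanged anyway.

The traversal keeps the `n` feature-wise matrices plus a stack of at most
`n` cumulative matrices (`2n` total, O(n·m²) memory; an instrumented
counter verifies the bound in tests). Advancing from signature `s`:

* last index `< n`: push `D_s + D_(last+1)` — one O(m²) addition;
* last index `= n`: pop the exhausted branch, replace the new last index
  `j` by `j+1` (two pops, one push).

A full enumeration therefore costs exactly one matrix addition per visited
subset (`2^n − 1` additions, against `Σ |s|·m² = n·2^(n−1)·m²` scalar
entries de novo). Stack slots are reused in place without zeroing; the
matrix passed to the visit callback is a view that is invalidated by the
next step, and callers who keep it must copy. Starting at an arbitrary id
rebuilds the parent-path stack with at most `n` additions, which is what
makes contiguous id-range chunking (and parallel screening) exact and
cheap.

Numerical error of a cumulative matrix is bounded by its path depth — at
most `n` additions of nonnegative terms, never `2^n` — so agreement with
the de-novo oracle is asserted at 1e−9 relative tolerance, a deliberately
loose engineering bound for float64 at n ≤ 62.

## k-NN cross-validation and the lookup table

The classifier is a plain majority-vote k-NN read off precomputed distance
rows. Two deterministic tie rules are fixed once and applied identically
in every code path, because the exactness guarantee below is unprovable
without them:

* distance ties — broken by ascending sample index (stable sort);
* vote ties — the label earliest in first-appearance encoding order wins.

An r×f fold plan assigns each sample to one fold per run (sizes differ by
at most one; runs use independent child streams of one seed). Folds are
not stratified by class: the closed-form lookup analysis assumes uniformly
random splits. The per-run error is the fraction of the `m` samples
misclassified when held out; the CV error is the mean over runs.

`cv_error_fast` precomputes each sample's k global nearest neighbors
(self excluded). A held-out sample whose k global neighbors all lie in the
current training folds has — provably, given the shared tie rules — a
local neighborhood identical to the stored list, so its prediction equals
its leave-one-out prediction and is read off the table. Any partial hit
falls back to a full scan of the training folds. Predictions are therefore
*identical* to the naive engine, prediction for prediction; the tests
assert this across randomized datasets, including degenerate ones with
exact distance ties. Leave-one-out is the `f = m` special case in which
every lookup succeeds, and is computed directly from the table.

## Lookup probability and the CV error bound

For equal folds (`|S|` divisible by `f`, `|T| = |S|(f−1)/f`), the number
of a test sample's global neighbors found in the training set is
hypergeometric `HG(k, |S|−1, |T|)` with mean `k|T|/(|S|−1)`; the all-k
success probability is

    p_lo = Π_{i=|T|+1}^{|S|−1} (1 − k/i),

computed as a left-to-right product of factors in (0, 1] (numerically
stable; the combinatorial binomial form is kept as an independent oracle
in the tests). Conditioning the expected CV error on the all-k event gives

    E_F[R̂_cv] = p_lo·R̂_lo + (1 − p_lo)·E_F[R_u],

with `R_u` the unknown error of off-lookup predictions; bounding
`R_u ∈ [0, 1]` yields the interval
`[p_lo·R̂_lo, 1 + p_lo·(R̂_lo − 1)]` of width `1 − p_lo`, exact at
leave-one-out. `R_u` is never estimated — only the extremal bound is
reported. When `|S|` is not divisible by `f` the canonical formula is
refused; a companion (`p_lo_uneven`) evaluates the product with each
fold's actual training size and returns the minimum over folds, a
conservative substitute that recovers the equal-fold value exactly when
sizes match. Probabilities are reported in percent rounded half-up to one
decimal; full precision is kept internally.

## Exhaustive screening

A screen draws **one** fold plan from its seed and shares it across all
subsets, so landscape differences reflect subsets only and a repeated
screen is bit-identical; whether folds should instead be re-drawn per
subset is a genuinely open design point, and sharing was chosen for
controlled comparison and reproducibility. The neighbor table, by
contrast, must be rebuilt per subset (global neighbors depend on the
subset's distance matrix), at `k|S|²` comparisons per subset.

Parallel screening splits the id range into equal-length contiguous
chunks — per-id cost is uniform (one addition, one CV), so id-count
balancing is load balancing. Chunks run on a thread pool; each owns its
private cumulative stack while the read-only feature-wise matrices are
shared, and results are concatenated in id order, making the landscape
identical for any worker count.

Selection is the arg-min of CV error with ties broken by subset size, then
id — the smallest equally good panel wins. Summaries report, per subset
size: count, min/max/median accuracy, and an accuracy histogram normalized
by its mode (default bin width 0.01, a conventional 1% grid), plus the
fraction of subsets whose accuracy is at least the full set's — an
indicator of whether selection can pay off at all on the dataset.
Landscapes are held in memory up to n = 30 (`2^30` records is the
practical ceiling); beyond that callers must screen explicit id ranges and
stream the chunks themselves.

The estimator facade (`ExhaustiveKnnSelector`) evaluates the criterion on
the data it is fitted on; nesting it inside an outer cross-validation
(e.g. `sklearn.model_selection.cross_val_score` around a pipeline) is
composition left to the caller.

## Synthetic data

Two generators stand in for real data in the tests:

* `simulate_uniform` — features i.i.d. U(0,1), labels round-robin and
  hence uninformative by construction. This emulates the null setting used
  for runtime and lookup-rate characterization: the chance-level error is
  known and any structure found is an artifact. How classes "should" be
  balanced in such null data is unspecified in general; round-robin is
  this package's choice, giving exactly balanced classes.
* `make_separable_fixture` — one planted feature with disjoint
  class-conditional supports (`[0,1)` vs `[1+gap, 2+gap)`) among uniform
  noise features; for `gap > 1` a 1-NN on the planted feature alone is
  LOO-error-free, giving a known arg-min for end-to-end screens.

Neither generator produces correlated features, heteroscedastic noise,
class imbalance, or label noise; passing tests demonstrate algorithmic
correctness (order, exactness, bounds, selection), not classification
performance on real biomedical data.

## Problem sizes in the test suite

Exhaustive oracle comparisons run where brute force is exact and quick:
codec bijection to n = 12, order-sort oracle to n = 8, traversal-vs-de-novo
at n = 6 / m = 10, whole-landscape naive-stack replay at n = 6 / m = 15.
Monte-Carlo checks use 1000–2000 random fold plans at m = 50 and 500
splits at m = 100 (3-standard-error acceptance). The end-to-end screen
runs the full `2^16 − 1` subsets at m = 50 with a 10×10 CV; the
work-count comparison against the de-novo baseline is instrumented at
n = 10. These sizes exercise every claimed property at scales where the
independent oracles are themselves trustworthy.

## Known limitations

* Numeric features only; the distance registry's per-feature kernel
  interface is the extension point for other per-feature data types.
* No heuristic searches (forward selection, genetic algorithms) — though
  codec + traversal are deliberately sufficient primitives to build them.
* No metric-tree indices (k-d/VP trees): in the target regime (moderate m,
  distances reused across thousands of subsets) precomputed matrices
  dominate them.
* The lookup path never reuses partial hits (fewer than k global neighbors
  in training) for prediction; that would trade exactness for speed.
* Distance matrices are dense float64; memory is O(n·m²), comfortable to
  m of a few thousand.
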