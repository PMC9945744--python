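# Methods

This note documents the models, conventions and numerical choices behind
`l3npred`, and what the synthetic experiments do and do not demonstrate.

## Graph model

A PPI network is an undirected simple graph over opaque, case-sensitive
string identifiers. Adjacency is stored as hash sets, so neighbor-set
membership is O(1) and building the L3-elements `(U, V)` of one candidate
pair costs O(|N(x)|·|N(y)|) — the scan over `a ∈ N(x)`, `b ∈ N(y)` testing
each `{a, b}`. Self-loops are rejected at construction; raw datasets with
self-interacting proteins are cleaned at load time instead. Networks are
treated as immutable while being scored; the simulations edit a copy, so
repeat bands are reproducible.

A P4 between `x` and `y` is a *simple* path `x–u–v–y` with `u ∈ U`,
`v ∈ V`, `{u, v}` an edge. A node in `U ∩ V` may act as `u` in one path
and `v` in another, but never both roles in the same path (`u ≠ v` is
automatic: there are no self-loops, and non-adjacency of the pair keeps
`u ≠ y`, `v ≠ x`).

## Predictors

All scores are symmetric in `x, y` and non-negative. Conventions that the
formulas themselves do not fix:

* **Zero-denominator rule.** Any similarity metric whose denominator set is
  empty returns 0 — the conservative no-evidence value; it keeps every
  score finite and makes empty-neighborhood candidates rank last.
* **Adamic-Adar logarithm.** Natural log; a common neighbor with degree ≤ 1
  would contribute an infinite/undefined term and is skipped (such a node
  cannot exist — a common neighbor has degree ≥ 2 — so this is a guard,
  not a modelling choice).
* **Factor hoisting.** In L3N/L3N′ the two outer factors `f(N(x),U)`,
  `f(N(y),V)` do not depend on `(u, v)` and are evaluated once; the four
  inner factors depend on only one of `u, v` each and are cached per node.
  This changes the cost, not the value: the test suite checks the optimized
  path against a straight-from-the-formula evaluator with no caching.
* **Ranking and ties.** `score_all_candidates` enumerates every unordered
  non-adjacent pair (an optional fast path for L3-family predictors scores
  only pairs joined by at least one P4 and appends the rest as a
  zero-score tail). Pairs with equal scores are permuted by a seeded
  shuffle before a stable sort — the same protocol as the random control —
  so precision–recall curves are never order-of-insertion artifacts.
  Zero-score candidates are kept in the ranking; they cannot overtake any
  positive-score pair.

## Ideal-L3-graph simulations

The ideal L3 graph with parts of size `nU`, `nV` has `nU + nV + 2` nodes
and `nU·nV + nU + nV` edges. Its perturbation universe is partitioned into
*compatible* edges `{u_i, v_j}, i ≠ j` (removal degrades evidence
gracefully; the `min(nU, nV)` index-matched edges are protected so the
L3-elements never change, which the removal loop asserts at every step) and
*incompatible* edges (`{u_i, u_j}`, `{v_i, v_j}`, `{x, v}`, `{y, u}`)
whose insertion corrupts the structure. Rectangular parts are supported;
the square case is the canonical one.

The insertion protocol recomputes `U` and `V` from the current graph at
every iteration, because the set definitions are functions of the graph and
`{x, v}` / `{y, u}` insertions genuinely move nodes between roles. A
`freeze_elements` flag pins `(U, V)` to the ideal parts for the alternative
reading; the two disagree on any trajectory long enough to touch an
endpoint edge, which is itself covered by a test.

Traces are normalized by dividing each repeat-trajectory by its own
maximum: all scores are non-negative, and along a removal trajectory the
ideal graph is the maximum, so removal curves start at exactly 1. Trace
AUCs use the trapezoidal rule on the median trajectory with the x-axis
rescaled to [0, 1]; the partial variant integrates from the argmin of the
median to the end (how fast a predictor's score rebounds after its dip).
Savitzky-Golay smoothing (window 21, degree 3) is available for plotting
but statistics are computed on unsmoothed data by default.

Simulation seeds expand from one root seed by integer arithmetic
(`root·1000003 + stream·524287 + repeat`, reduced mod 2³¹−1); Python string
hashing is process-salted and is never used for seeding.

## Synthetic data generators

* **Duplication-mutation networks.** Grown from a seed triangle by
  repeatedly duplicating a uniformly chosen node; the duplicate inherits
  each parent edge with probability `p_keep` (default 0.7) and gains an
  anchor edge to its parent with probability `p_anchor` (default 0.1), the
  standard duplication–mutation-with-complementarity null model for
  heavy-tailed, P4-rich interactomes. A duplicate that would be born
  isolated is anchored to its parent so the network stays usable for
  evaluation. Defaults sit in the regime where the degree tail is visibly
  heavier than an equal-density Erdős–Rényi graph, which a test checks.
* **Gadget networks.** Unions of ideal-L3 gadgets, each completed with its
  true `{x, y}` edge, plus optional uniform cross-gadget noise edges. These
  provide ground truth for end-to-end recovery: hide the gadget edges,
  rank all candidates, walk the precision–recall curve.

What these generators emulate is the *topological* signal the predictors
consume — heavy-tailed degrees, abundant P4s, planted near-ideal L3
neighborhoods. They do not emulate study bias, false-positive edges from
specific assay types, protein families or any node metadata, so passing
tests demonstrate correctness and relative sensitivity of the predictors,
not absolute performance on any real interactome.

## Evaluation harness

Monte-Carlo splits remove `round(fraction·m)` edges uniformly at random,
independently per repeat; k-fold CV partitions edges into balanced folds
(disjoint, exhaustive). Negative-PPI injection *replaces* a fraction of
training edges with uniformly sampled non-edges of the full network
(rejection sampling), holding the training edge count fixed; corrupted
true edges do not join the hidden ground-truth set, which scores recovery
of the originally removed edges only.

Precision–recall curves classify every ranked candidate individually
(tp if hidden, else fp; `fn = |hidden| − tp`), stop early at an optional
recall cap, and integrate by the trapezoidal rule with an anchor point at
recall 0 carrying the precision of the first step — so a perfect ranking
has AUC exactly 1. The mean relative ΔPR-AUC across a grid of corruption
ratios is the mean over consecutive ratio steps of
`(mean_next − mean_prev)/mean_prev`; per-repeat slopes normalised by
baseline would be an alternative reading, and the chosen statistic is the
simpler of the two. Significance between AUC samples uses the two-tailed
independent two-sample t-test, with p = 1 by convention for two identical
zero-variance samples.

## Problem sizes

The shipped experiments run at desk scale: sensitivity simulations on a
20+20 ideal core with 5 repeats, oracle cross-checks on 100 random graphs
of ≤ 25 nodes, evaluation and sampling-equivalence checks on
duplication-mutation networks of 80–400 nodes, and recovery on six-gadget
networks (~60 nodes). These sizes were chosen so the full suite runs in
seconds to minutes while leaving every qualitative conclusion — the
sensitivity ordering, the recovery margin, the sampling-scheme equivalence
— comfortably away from its threshold.

## Known limitations

* Predictor scoring is single-threaded pure Python; the complexity is the
  right one (hash-set preprocessing, per-pair O(|N(x)|·|N(y)|) work) but
  large interactomes (10⁵+ edges) will be slow in absolute terms.
* `inject_negatives` samples non-edges by rejection, which is efficient on
  sparse networks and degrades as density approaches saturation.
* The column filter in the edge-list reader is a generic
  (index, accepted-values) predicate; database-specific dialects
  (PSI-MITAB, BioGRID TAB) are intentionally out of scope.
* Weighted, directed and multi-edge graphs are unsupported by design.
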