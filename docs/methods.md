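# Methods

## Model

`netprio` ranks candidate disease genes on a weighted gene
functional-association network by a three-step procedure: raw
shortest-path distances, a centrality adjustment, and a
guilt-by-association weight converted to a precision score.

**Raw distance.** Each edge's confidence score *S* ∈ (0, 1000]
(integer, STRING `protein.links` convention) is mapped to a length
*D* = 1000/*S*: confident interactions are short, weak ones long. The
distance between any two genes is the weighted shortest path, computed
exactly with Dijkstra's algorithm from every source
(`scipy.sparse.csgraph`). The resulting matrix is a metric — symmetric,
zero diagonal, triangle inequality — and every off-diagonal entry is at
least 1 because a single edge costs at least 1000/1000.

**Centrality profile.** μ<sub>a</sub> is the mean raw distance of gene
*a* to all *N* genes, with the zero self term included and divisor *N*.
Including the self term biases μ down by a factor (N−1)/N uniformly;
since every use of μ is relative, this convention choice is harmless,
and it keeps the definition a plain row mean. Small μ identifies hub
genes.

**Adjusted distance.** The default (geometric) form is
D̂<sub>ab</sub> = D<sub>ab</sub> / √(μ<sub>a</sub>μ<sub>b</sub>). Two
variants are provided and selectable everywhere the adjustment appears:
arithmetic, 2·D<sub>ab</sub>/(μ<sub>a</sub>+μ<sub>b</sub>), and
product, D<sub>ab</sub>²/(μ<sub>a</sub>μ<sub>b</sub>). All three are
symmetric, nonnegative, zero-diagonal and invariant under uniform
rescaling of the raw distances. The geometric form is the default
because it is the canonical dimensionless normalization by two
reference scales and treats the endpoints symmetrically in the
multiplicative sense; the choice is a configuration parameter rather
than a hard-coded commitment precisely because reasonable readers can
prefer either mean.

**Disease weight.** For a disease gene set of size *K*,
w<sub>i</sub> = (1/N)Σ<sub>j</sub>D̂<sub>ij</sub> −
(1/K)Σ<sub>j∈disease</sub>D̂<sub>ij</sub>. A ratio variant
(first component over second) is available behind a flag for
sensitivity analysis; the difference form is the default and the one
all evaluations use. Both components include the gene's own zero
self term when it applies; a consequence worth knowing is that a gene
exactly equidistant from every other gene has w = −c/N (not 0): the
self term enters the all-genes mean but only enters the disease mean
when the gene is itself a disease gene.

**Score conversion.** Weights are disease-specific; to compare across
diseases each weight is mapped to the precision TP/P among genes
weighing at least as much (inclusive threshold — an exclusive reading
would leave the top-ranked gene with an undefined 0/0 precision). The
conversion is stepwise, not interpolated, and deliberately not
monotonized: precision can dip below a better threshold's value, which
is informative. An isotonic (running-max) variant exists but is off by
default. At the weakest threshold the score is exactly K/N, the
prevalence.

## Evaluation protocol

**LOOCV.** Each disease gene is held out in turn; weights are retrained
on the remaining K−1 genes and the held-out gene's weight and
genome-wide rank (descending weight, ties broken by gene id) are
recorded. Non-disease genes are scored once against the full K-gene
set: re-scoring all N−K negatives inside every fold would multiply the
cost by K while changing nothing about the question the protocol asks
of the negatives, whose training set never loses a member.

**PR curve.** Thresholds sweep the distinct scores in descending
order; tied scores enter together. Precision = TP/(TP+FP), recall =
TP/K. The area is a trapezoid over recall, anchored at (recall 0,
precision of the strictest threshold) so a perfect ranking scores
exactly 1. F-max is the maximum F1 over all thresholds, endpoints
included. The implementation is cross-checked in the test suite
against scikit-learn's `precision_recall_curve` on the shared points.

**Null calibration and the small-K bias of AUPRC.** Under random
scores the *expected precision at any fixed threshold* equals the
prevalence K/N, but the area estimator itself is not unbiased: recall
increments coincide with positives, where conditional precision is
elevated, so with few positives the AUPRC null distribution is
right-skewed with mean above prevalence (measured ≈1.13× at K = 15,
N = 300, shrinking toward 1 as K grows — ≈1.01× by K = 120). This is a
property of every stepwise PR-area estimator we measured (anchored
trapezoid, average-precision step rule, interpolated area), not of one
integration choice. Calibration checks therefore compare the *median*
of the permutation-null distribution to prevalence (within 3 bootstrap
standard errors of the median); the median sits at ~1.02× prevalence
throughout. The cohesion-0 network null compares means across 20
independently generated networks, where the Monte-Carlo SE dominates
the bias.

**TPR@k.** The fraction of the top k genes (LOOCV scores, positives
judged by their held-out score) that are known disease genes — a
precision-like reading matching "how much of a k-gene assay budget
would hit". A recall-like variant (divide by K instead of k) is
available behind a flag.

**Rank ratio.** A gene's rank divided by the number of ranked genes;
lower is better. Off-component genes are never ranked and are excluded
from the denominator.

**Pooling.** Converted precision scores (not raw weights) are pooled
across diseases into one labeled list for a combined PR curve, since
only the converted scores live on a shared scale.

## Synthetic data

`SyntheticScenario` defaults describe the regime the method is built
for: N = 300 genes, Erdős–Rényi background with edge probability 0.02
and confidence ~N(200, 50) — sparse, weak background association — and
one planted 15-gene module with edge probability 0.8 and confidence
~N(900, 50): a compact, high-confidence disease module occupying 5 % of
the genome. Scores are rounded to integers and clamped to [1, 1000].
A `cohesion` parameter interpolates the module's edge probability and
confidence linearly toward the background values; cohesion 0 is the
null in which "disease genes" are indistinguishable from background.
If a draw leaves the graph disconnected, stray components are chained
to the main one with fixed low-confidence (S = 100) backbone edges so
distances are finite everywhere; this adds a negligible number of long
edges and keeps generation deterministic.

What the generator does *not* emulate: STRING's heavy-tailed degree
distribution, its evidence-channel structure, correlated edge noise,
and diseases whose genes are scattered rather than modular. Passing
tests on planted modules therefore demonstrate correctness of the
machinery and recoverability in the compact-module regime, not
performance on real disease annotations — diseases with interspersed
genes are exactly where the adjustment is expected to help least, and
the raw-vs-adjusted comparison reports the mean pairwise disease-gene
distance so that regime is visible.

**Hub fixture.** A designed, deterministic network for exercising the
centrality correction: one hub wired to every leaf at S = 1000, an
8-gene module clique at S = 500, and ~half of the remaining leaves
hanging off single module genes as "satellites" at S = 700. Raw
distances rank the hub immediately after the module (it is one strong
hop from everything); the adjustment divides the hub's distances by
its very small √μ, demoting it below the satellites, whose large μ
works in their favour. The fixture's scores were chosen so this
crossover is structural, with comfortable margins, rather than
balanced on a knife edge.

## Numerical choices

- Distances are computed in float64. Per-source Dijkstra can differ in
  the last ulp between directions (different summation order), so the
  matrix is symmetrized by taking the elementwise minimum of the two
  directions.
- The on-disk distance cache stores float32 values (the O(N²) matrix
  dominates storage; 7 significant digits comfortably exceed the
  meaningfulness of 1000/S path sums). μ and adjusted matrices are
  recomputed from the cached values on load, so everything derived
  from one cache is mutually consistent.
- Exactness tests against the brute-force Floyd–Warshall oracle draw
  confidence scores from divisors of 1000, making 1000/S and all path
  sums exactly representable in binary floating point; with arbitrary
  scores agreement is asserted to 1e-12 relative instead.
- Disconnected inputs: all computation is restricted to the largest
  connected component (ties broken toward the earliest-loaded gene);
  off-component genes carry no weight and are appended to rankings
  flagged `unranked`. Infinite distances would otherwise poison every
  mean.
- Ties in ranking are broken by ascending gene id, making every
  ranking and every downstream metric deterministic.
- Duplicate edge rows merge to the maximum confidence; self-loops are
  dropped at parse time (their gene is still registered).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `min_score` | 1 | confidence floor at network load; STRING tier presets 150/400/700/900 exported as `STRING_SCORE_TIERS` |
| `normalization` | `geometric` | form of the centrality adjustment |
| `weight_mode` | `difference` | how the two mean-distance components combine |
| `inclusive_threshold` | `True` | a gene's own weight counts at its threshold in score conversion |
| `p_threshold` | 5e-8 | genome-wide significance, strict inequality |
| `top_n` | 500 | rank cutoff for flagging novel SNP host genes |
| `ks` | 50/100/150/200 | TPR@k report points |

## Known limitations

- Dense O(N²) distance storage and all-pairs Dijkstra limit practical
  use to networks of a few tens of thousands of genes; no
  landmark/approximate shortest paths are provided by design.
- Gene identifiers are opaque strings; no mapping between identifier
  namespaces is attempted.
- The precision score is a descriptive quantity, not a significance
  level; no p-values or FDR are attached to ranks.
- LOOCV negatives are scored once (see above); a protocol that
  re-scores negatives per fold would differ in the tails when K is
  large relative to N.
- SNP-to-gene assignment is taken as an input column; no variant
  consequence annotation or LD handling.
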