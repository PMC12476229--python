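# Methods

This note records the models behind each metric family, the defaults and
the numerical choices made where the underlying definitions leave room,
and what the synthetic generators do and do not emulate.

## Partition metrics

All pair-counting metrics are computed from the class × cluster
contingency table; the pair quantities are a = Σ C(n_ij, 2),
a + b = Σ C(a_i, 2), a + c = Σ C(b_j, 2) with d the remainder of
C(n, 2). Chance adjustment uses the generalized hypergeometric
(permutation) model wherever a closed form exists: E[WH] = Σ C(a_i, 2) /
C(n, 2), E[WC] = Σ C(b_j, 2) / C(n, 2), and the expected mutual
information is the exact sum over per-cell hypergeometric laws (computed
with log-factorial tables for numerical stability). With these
expectations, ARI is algebraically the harmonic mean of AWH and AWC; the
test suite asserts this identity exactly.

Conventions for degenerate inputs: two identical partitions score ARI 1
even when both are a single group; undefined denominators (all-singleton
Wallace indices, single-group adjusted expectations) raise a typed
`UndefinedMetricError` rather than returning NaN. Entropies default to
base 2 (bits); every ratio (EH, EC, VM, NMI) is base-invariant. NMI uses
the arithmetic normalizer by default so that it coincides with the
V-measure at β = 1; AMI uses the same normalizer for consistency. When
the prediction is a single cluster, EH = 0 and EC = 1 (zero-entropy
convention); both-trivial inputs score 1 across the suite.

The class-size-normalized Rand index (NCR) is specified in the
literature only descriptively, so the construction here is an
interpretation and is documented as such: for each ground-truth class X,
concordant pairs involving X (within-class pairs kept together plus
(X, non-X) pairs kept apart) are divided by all pairs involving X, the
unweighted mean over classes is taken, and the result is chance-adjusted
as (M − E)/(1 − E) with E estimated from seeded permutations of the
predicted labels (default 200). Because each class is normalized by its
own pair count, one misassigned element costs more in a small class —
the behavior the index exists to provide.

Note on a stated relationship: RI is sometimes described as the harmonic
mean of WH and WC, but algebraically RI = (a + d)/C(n, 2) while the
harmonic mean of the Wallace indices is 2a/(2a + b + c); the two differ
whenever d > 0. The package therefore reports both quantities and does
not assert that identity anywhere.

## Embedding metrics

Silhouette widths use exact pairwise distances; cosine distance is
implemented by row normalization (zero-norm rows are left as-is) so that
it is invariant to per-element positive rescaling — the mechanism by
which library-size variation inflates euclidean but not cosine
distances. Members of singleton groups score 0 (the common convention;
the definition is silent).

CDbw = cohesion × compactness × separation. Representative points are
chosen farthest-first (seeded at the point nearest the centroid, ties to
the lowest index), default 10 per cluster, clamped with a warning.
Shrink factors default to 0.1…0.8 in steps of 0.1. The density kernel
around a (shrunken) representative is left open by the definition; here
it counts cluster members within one cluster standard deviation (the RMS
of per-dimension standard deviations) and divides by cluster size, which
makes compactness scale-invariant while separation scales linearly with
the coordinates. Between-cluster distance and density use *respective
closest representatives* — mutually nearest representative pairs — as in
the original construction; pairing every representative with its
one-sided nearest partner dilutes the separation signal enough to invert
the expected ordering on interleaved-moons labelings, which is why the
mutual rule is used. Inter-cluster density is the mean over clusters of
the maximum pairwise between-density; separation divides the mean
nearest-cluster distance by 1 + that quantity.

DBCV uses the all-points core distance
(mean over same-cluster neighbors of (1/dist)^d)^(−1/d) with d the
embedding dimensionality; zero distances (duplicate points) are excluded
from the mean, and an all-duplicates cluster scores 0 validity with a
warning. The density sparseness of a cluster is the maximum edge of the
minimum spanning tree built on within-cluster mutual reachability; the
density separation between clusters is the minimum cross-cluster mutual
reachability, with each object keeping its own within-cluster core
distance. Exact pairwise distances are used throughout (the intended
regime is n up to a few thousand embedding points).

## Graph metrics

kNN graphs include every neighbor tied at the k-th distance (inclusive
rule, with a 1e−9 relative tolerance so exact geometric ties survive
floating-point), then symmetrize by union; a mutual-kNN flag is
available. SNN weights are Jaccard overlaps of the two kNN sets;
zero-overlap edges are dropped. LISI is the plain inverse Simpson index
of the class mix over a node's neighbors (no kernel weighting, matching
the neighborhood-sampling description; the perplexity-weighted variant
used by harmonization tools is intentionally not the default). PWC uses
weighted degrees and a strict inequality — a node is weakly connected
only when its outside degree exceeds its inside degree. Modularity is
the standard resolution-γ form on the weighted adjacency. Cohesion and
adhesion are vertex/edge connectivity via max-flow (networkx).

AMSP of a class subgraph: mean all-pairs shortest path divided by √N
when connected; Σ over components of (1 + mean within-component shortest
path) divided by √N when disconnected, single nodes contributing 1.
Hops are used unless edge weights are requested. Note the stated lower
bound of 1 for this score only holds in sparse kNN regimes — a complete
graph scores 1/√N — so the package does not enforce it as an invariant.

One property worth recording: modularity under a random-label null is
*not* mean-zero. Because self-pairs always count as within-community,
E[Q] = (Σ k_i²/(2m)²)(p − 1) < 0 for label-permutation probability p of
two nodes sharing a label; the test suite checks the analytic value
rather than zero.

## Fuzzy pair-counting metrics

Membership rows must sum to 1 (tolerance 1e−9). Pair agreement within a
partition is A_ij = ‖w_i − w_j‖₁/2 and cross-partition pair concordance
C_ij = 1 − |A_ij^P − A_ij^Q|; NDC is the mean of C over pairs and
reduces exactly to RI on one-hot inputs (the implementation detects hard
inputs and takes the contingency-table fast path, which is bit-identical
to the generic blocked computation). Fuzzy Wallace indices weight C_ij
by the pair's class membership under a t-norm — product by default,
minimum available — with completeness weighted by the truth memberships
and homogeneity by the prediction memberships. Chance adjustment
permutes the rows of the predicted membership matrix (seeded, default
100 permutations) and applies (M − E)/(1 − E); applied to NDC this gives
the ACI. Which side is permuted is configurable (`pred`, `truth`,
`both`); the default permutes the prediction, consistent with the
Wallace adjustment recipe. All pair sums run in fixed-size row blocks
(default 1024), so memory stays O(block · n).

## Spatial metrics

Spatial neighborhoods use the median-radius rule: the radius is the
median over spots of the distance to the k-th nearest neighbor (default
k = 6; k = 4 recovers rook adjacency on unit grids), and neighbors are
all spots within that radius. Border spots simply have fewer neighbors;
isolated spots are flagged and excluded from scores that need a
neighborhood. Label smoothing blends each spot's one-hot label with its
neighborhood's label fractions, w = α·self + (1 − α)·neighborhood, with
α = 0.5 by default so a spot contradicted by its entire neighborhood
retains exactly half of its own-label membership.

The neighborhood-smoothed (ns*) metrics use the fuzzy-hard mode: the
prediction stays hard, the truth enters both hard (Q) and smoothed (R),
and each pair takes the more favorable concordance,
C = 1 − min(|A^P − A^Q|, |A^P − A^R|), so a prediction identical to the
hard truth still scores 1. Wallace pair memberships come from the hard
labels. Adjusted ns* metrics subtract a seeded permutation null of the
predicted labels (smoothing is recomputed only on the truth, which is
fixed, keeping the cost at O(n_perm · pairs)).

Distance-weighted spatial RI: concordant pairs score 1; wrongly grouped
pairs score f(d), wrongly separated pairs h(d), with d the euclidean
distance on per-axis min–max normalized coordinates. Two decay modes are
provided: the original f(d) = α·exp(−d²), h(d) = α(1 − exp(−d²)) with
α = 0.8, and the steeper default f(d) = α·exp(−β_f·d),
h(d) = α(1 − exp(−β_h·d)) with β_f = 4, β_h = 1. At α = 0 the metric
equals the classical RI exactly. The pair sum is streamed in O(1) memory
by a compiled kernel — no n × n matrix is ever materialized — which is
what lets the metric run at 10^5+ spots where dense implementations
exhaust memory. For the chance-adjusted spatialARI the package uses the
*exact* expectation under the permutation null rather than Monte-Carlo
permutations: a uniformly permuted prediction merges every pair with the
same probability q = Σ m_c(m_c − 1)/(n(n − 1)), so E[spatialRI] is a
per-pair linear functional accumulated in the same single pass. This is
deterministic, seed-free, and removes both the Monte-Carlo error and the
factor-of-n_perm cost that would make the metric unusable at scale.

PAS flags a spot as abnormal when a strict majority of its neighbors
carries a different label. CHAOS is the mean 1-nearest-neighbor edge
length per domain on normalized coordinates, averaged across domains
(singleton domains skipped with a warning). ELSA multiplies a
dissimilarity term E_a (mean category dissimilarity to the neighbors,
scaled by the maximum dissimilarity) by a diversity term E_c
(neighborhood category entropy normalized by log₂ of the attainable
category count m_i = min(m, neighborhood size)). For unordered domain
labels a rank-based category dissimilarity is arbitrary, so the default
is binary (d = 1 between any two distinct categories); rank-based and
user-supplied matrices are options. The focal spot is excluded from its
neighborhood's category mix by default (the neighbor sums run over
j ≠ i), with a flag to include it. Neighborhoods with a single
attainable category get E_c = 0.

SPC assigns each spot the fraction of its pairs that are concordant; the
dataset mean equals RI exactly, and all spots sharing a (class, cluster)
combination share a value, which is computed in closed form from the
contingency table. The negative-pair-excluding variant drops pairs
separated in both partitions from the denominator. Spatial SPC replaces
the hard pair indicator with the fuzzy-hard concordance above.

nsAccuracy matches predicted clusters to classes one-to-one (Hungarian
matching on the contingency table, maximizing matched counts, with
lexicographically-smallest tie-breaking; skipped when the label
vocabularies already coincide). Correct spots contribute 1; a
misclassified spot contributes the fraction of its spatial neighbors
whose *true* class equals the spot's predicted class — the description
of the neighborhood term is ambiguous between true and predicted
neighbor labels, and the true-label reading is the default because the
score is meant to measure agreement with the truth of the neighborhood;
a flag selects the alternative. Misclassified isolated spots contribute
0 with a warning.

## Synthetic data

`mock_data` places class centroids by classical (Torgerson) MDS on a
requested pairwise-difference matrix — negative eigenvalues are
truncated with a warning, falling back to the best rank-d fit — and
samples points around them with a per-class spread mode: isotropic
normal, median-centered log-normal (right-skewed), or a symmetric
two-component shift mixture producing elongated non-Gaussian classes.
Defaults are 3 classes × 100 points, pairwise difference 10, standard
deviation 1, in 2 dimensions. Descriptors follow the usual summaries:
size imbalance is the Simpson diversity 1 − Σ p² of the class
abundances, signal-to-noise the ratio of mean pairwise difference to
mean class standard deviation (+inf with a warning at zero variability),
spread the mean class spread parameter.

`gaussian_scenarios` contrasts globular against elongated two-class
layouts at matched centroid separation (the elongated one produces
negative silhouette tails). `moons` generates interleaved half-moons
with the generating labels and a deterministic straight-cut labeling
standing in for what a centroid-based clustering does to this geometry
(a fixed cut rather than an actual k-means run keeps the fixture
dependency-free and bit-reproducible). `grid_toy` builds two-domain
grids (blocks, stripes, checkerboard) and, for the blocks layout,
prediction variants that flip the same number of domain-A spots to B
either along the interface or at interior positions ≥ 2 cells from the
interface, ≥ 1 from the field border and ≥ 3 apart — so all variants
share one confusion matrix (partition metrics identical by
construction) while each interior error is an isolated island with an
identical local configuration (spatially aware raw scores exactly
invariant across interior placements).

These generators emulate geometry and spatial layout only: there are no
counts, no dropout, no batch effects, no real tissue morphology. Passing
tests therefore demonstrate the metrics' mathematical behavior
(identities, bounds, orderings, chance neutrality), not performance on
real data.

## Problem sizes and numerics

The test suite uses n ≤ 200 for distributional checks (500 replicates
for chance neutrality), 100 random instances for the exact reduction
identities, and a single 150,000-spot grid to exercise the streaming
spatial kernel; the acceptance script uses the constructed inputs listed
in its docstring. Exact identities are asserted to 1e−12…1e−14;
Monte-Carlo means to 3 standard errors. Hungarian matching resolves
score ties toward the lexicographically smallest (cluster, class)
assignment so all matching-based outputs are reproducible. Every
stochastic routine takes an explicit seed and is bit-reproducible given
it.

## Known limitations

- Coordinates are 2D only; 3D spatial data is out of scope.
- Exact pairwise-distance computation bounds the practical embedding
  metric size at a few thousand points; the pair-counting and spatial
  kernels scale much further (blocked / streaming).
- The NCR construction is an interpretation of a descriptive definition
  (see above) and its permutation-estimated expectation carries
  Monte-Carlo error controlled by the permutation count.
- Fuzzy metrics are exact O(n²) by default; a seeded pair-subsampling
  estimator with a standard error (`ndc_subsampled`) is available for
  very large n and is clearly approximate.
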