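# Methods notes

## The missing-data model

A phospho-matrix cell is either an observed nonnegative spectral count
(zero included — an observed zero is data) or missing. Missingness is
treated as non-informative absence: no imputation of values is ever
attempted, because in these matrices missing cells outnumber data by
~20:1 and any value model would dominate the signal. All statistics are
computed over observed cells only; the single place missing cells enter
numerically is the slope-culling regression (below), where absence in a
high-signal sample is itself evidence against pattern conformity.

## Distances

*Pairwise-complete correlation.* For each gene pair the correlation is
computed over the samples observed in both genes; Spearman is the
default (counts are not plausibly linear), Pearson an option. The
distance is `1 − |r|`: perfect anticorrelation is as informative as
perfect correlation. A pair with fewer than `min_overlap` (default 2)
co-observed samples, or zero variance on the overlap, has no defined
correlation and yields a missing distance. Note that with the default
minimum the correlation over exactly 2 points is always ±1, so a chance
2-sample overlap produces a spurious zero distance; raising
`min_overlap` to 3 trades these false links for more missing pairs.
The implementation delegates to pandas' pairwise-complete `corr` (ranks
are re-derived per pair, average ranks for ties); the test suite holds
it to within 1e-12 of an explicit per-pair brute-force loop.

*Euclidean.* The partial sum of squares over the m co-observed of p
samples is rescaled by p/m before the square root, following the
convention of the classic `dist` implementations; m = 0 gives a missing
distance. Whether to rescale or drop incomplete pairs outright is
genuinely open; the rescaling is the documented default because it keeps
sparse and dense pairs on one scale. Manhattan and Canberra variants
exist behind `metric_distance` (reported nearly indistinguishable from
Euclidean on this class of data; untested beyond unit level).

*Zero-imputation mode.* Every distance function accepts
`missing_policy="zero_impute"`, which zero-codes missing cells first.
This mode exists only as the negative control: shared zeros correlate,
the distance distribution collapses (the pairwise-complete IQR strictly
exceeds the zero-imputed IQR in the regression test), and planted
structure is recovered worse.

## Fill and the SED

Missing distances mean "no statistical relationship" and must read as
*far* for clustering: they are set to `fill_factor` (default 100) times
the maximum real distance of the matrix. Order matters: fill first, then
scale — each filled matrix is divided by its own maximum *real*
distance, so real distances land in [0, 1], fills equal `fill_factor`,
and the SED is the entrywise mean of the two scaled matrices. A pair
filled on one side only averages to ≈ fill/2: half the evidence says "no
relationship", and the pair stays far.

Fill-factor insensitivity is exact for MST single-linkage extraction
from the distance matrix, because only the rank order of distances
enters and fills remain the unique maximum for any factor > 1 (the
acceptance suite asserts bit-identical partitions at factors 100 and
1000). Through the t-SNE map the statement is only approximate: the
optimizer sees the fill magnitude, and maps at different factors differ
in detail while preserving the same coarse structure.

## Embedding

The filled dissimilarity matrix is used as a *dissimilarity
representation*: each gene's row is its feature vector, and t-SNE embeds
those vectors with no attempt to preserve the distances themselves. This
choice is load-bearing — nearest-neighbour purity of planted clusters in
feature space is ~0.85 on the default synthetic matrices versus ~0.28 in
the raw SED metric. Classical (Torgerson) MDS on the distances is
provided for comparison and for coordinate layouts; it is deterministic
up to sign, warning and zero-padding when the requested dimensions
exceed the positive eigenvalue count.

t-SNE defaults follow the established setup for these data: 2–3 output
dimensions, perplexity 30, 1000 iterations with no early stopping
(`min_cost = 0` maps to a zero gradient-norm threshold), optional
whitening = centering + PCA to `initial_dims` (30) components with unit
component variance.

**Whitening caveat.** Whitening is appropriate for matrices with
thousands of genes, where 30 components are a small, signal-dominated
subspace. At a few hundred points it is actively harmful: variance
normalisation amplifies chance co-observation noise directions to equal
weight (measured 11-NN purity on the default synthetic matrices drops
from 0.85 to 0.52; a 24-point toy becomes pure noise). The benchmark
protocol therefore sets `whiten=False`; the configuration default stays
`True` for fidelity to the published setup at full scale.

## Cluster extraction

Clusters are connected components after cutting MST edges — exactly the
single-linkage dendrogram cut, which the test suite verifies against an
independent hierarchical-clustering oracle on random instances. Two
modes: cut all edges above a similarity radius (radius 3.5 is the
conventional "similar" scale on large t-SNE maps), or cut the k−1
longest edges for exactly k groups (the mode used for method
comparisons at fixed cluster count). Equal-length edges are cut in a
stable order (descending length, then lexicographic endpoint labels) so
partitions are reproducible; zero-length edges (identical points) are
handled by a constant weight shift that changes neither the MST nor the
cut order. For MDS embeddings no default radius is meaningful and
target-k is required.

k-means runs on the same feature vectors (10 restarts, best inertia);
fuzzy membership selection takes any gene × cluster score matrix and
keeps scores above mean + 2.5 sd per cluster (zero-spread clusters
select nobody, with a warning).

## The Index

`Index = intensity · (1 + realsamples) · (1 + cleargenes) / (1 + %NA)`
with the component definitions in the README. Percentages are carried at
full precision and only rounded in printed tables. Conventions at the
edges: slope exactly 0 keeps the gene (only a positive slope culls); a
single-sample cluster culls nothing (the slope is undefined); cluster
statistics are computed over the cluster's *own* samples — exactly those
containing at least one observed cluster gene — so a small cluster of a
233-sample dataset is scored over the dozens of samples it actually
occupies. The Index is strictly decreasing in %NA and strictly
increasing in cleargenes and realsamples (property-tested), and ranks a
dense cluster above an equally strong sparse one.

Heat-map ordering sorts genes by decreasing observed row sums and
samples by decreasing observed column sums, stable on ties; missing
cells render black. The published figures speak of "scaled" counts
without specifying the transform, so ordering uses raw observed counts
and any colour scaling is presentation-only.

## Wrangling

`combine_clusters` is set union with provenance. `filter_cluster`
applies rules in a fixed order — anchor sample restriction, gene rules
(minimum occurrence, single-sample genes, slope conformity), sample
rules (single-gene samples) — and iterates to a fixed point, because
dropping a sample can create new single-sample genes and vice versa.
Single-pass mode reproduces narratives that applied each filter once.
The anchor gene is never dropped. "Present at least twice" is read as
observed in ≥ 2 *kept* samples.

## Networks, backgrounds, GO

Undirected interaction evidence for a pair is summed into one edge;
kinase–substrate records form a separate *directed* edge class at a
fixed nominal weight (0.25) per record, because quantitative PPI scores
and curated directional facts are not commensurable and their published
composition is not specified. Total pair evidence reports both classes.

Random backgrounds draw gene sets of sizes 11–34, two per size (48
sets), from the supplied universe and record induced edges-per-node and
weight-per-node; the sources are internally inconsistent about the size
range, and 11–34 × 2 is the reading that yields the stated 48 sets.
Expected induced edges are computed under two null models — uniform
density `E·C(n,2)/C(N,2)` and degree-preserving configuration
`Σ k_i k_j/(2E)` — because the published formula did not survive into
the text; density is the default and the choice is a flag.

GO over-representation uses the hypergeometric upper tail against the
annotation universe, raw p < 0.01, and discards terms hit by a single
cluster gene (one gene is membership, not enrichment). No
multiple-testing correction is applied by default, matching the original
protocol; Benjamini–Hochberg is available behind a flag. The test suite
pins p-values to exact combinatorial enumeration on small universes.

## The synthetic generator

`simulate_phospho_matrix` emulates the structural features that make
this clustering problem hard: ~95% missing cells at the defaults
(300 × 60, checked against the closed-form expectation), right-skewed
counts (`ceil` of log-normal(1, 1), so counts are ≥ 1 and heavy-tailed
like phosphopeptide totals), and 10 disjoint 12-gene clusters co-observed
(p = 0.8) in 8-sample blocks against a p = 0.01 background. Because
10 × 8 sample slots exceed 60 samples, blocks cannot be disjoint in
samples; the default "cyclic" layout staggers them at even offsets over
a random sample permutation so each cluster overlaps only its two cyclic
neighbours — the closest realization of disjoint blocks, and a
pathway-sharing structure rather than arbitrary entanglement. A fully
random layout is available (`sample_layout="random"`); it entangles many
cluster pairs and makes recovery substantially harder. Rows whose
Bernoulli draws come up empty are redrawn (bounded, then forced), which
biases realized missingness slightly below the closed form — still
within the ±2-point tolerance asserted in tests.

What the generator does *not* emulate: correlated count values within a
pathway (counts are iid given the observation mask — recovered clusters
here are pure co-observation structure), peptide-level effects,
batch/run structure, and detection probability depending on abundance.
Passing recovery tests therefore demonstrates that the pipeline resolves
co-observation structure at realistic sparsity; they say nothing about
resolving expression-correlated but differently-observed pathways.

`simulate_interaction_network` plants edges within clusters
(p = 0.3) against a sparse background (p = 0.005) with log-normal
weights, for exercising the external-evaluation stage.

## Benchmark protocol and problem sizes

The recovery benchmark (`benchmark.run_recovery`, also the basis of the
acceptance checks) runs SED → t-SNE(2D, perplexity 30, whiten off — see
the whitening caveat) → MST at radius 2.0 on the default 300 × 60
simulation and scores ARI over the planted genes (background genes have
no planted identity). The radius was chosen the way such radii are
chosen — by inspecting maps from preliminary simulations: on ~300-point
maps planted clusters span ~2 units and sit a few units from their
neighbours, so the 3.5 convention calibrated on maps of a few thousand
points over-merges. Test problem sizes throughout (50 × 20 oracle
matrices, 100-point MST instances, ≤ 25-gene GO universes, 3-seed
recovery runs) are chosen so the whole suite runs in a couple of minutes
on one core while still exercising every code path at realistic
sparsity.

## Known limitations

* Single linkage chains: one stray point within the radius merges two
  clusters; the radius mode is therefore sensitive near dense
  background pools (use target-k for fixed-count comparisons).
* t-SNE map scale is n-dependent and has no absolute meaning at small n
  (well-separated groups repel without bound), so any fixed radius is
  calibrated to a map scale, not universal.
* The correlation minimum overlap of 2 admits ±1 correlations from
  chance 2-sample overlaps (see Distances).
* `percent_na`-style statistics depend on the cluster-restricted sample
  set; comparing clusters across very different sample occupancies
  compares different denominators.
* GO p-values are raw by design; with thousands of terms the retained
  set at p < 0.01 contains false positives, which is why the random-set
  background (terms-per-gene) is reported alongside.
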