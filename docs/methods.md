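# Methods

This note documents the model behind `nbrclust`, the defaults that matter,
the numerical conventions, and what the synthetic benchmarks do and do not
demonstrate.

## The clustering model

The framework treats clustering as a graph-resilience problem. Samples are
vertices of a proximity graph; a *cluster structure* exists exactly when a
small set of vertices holds the graph together, and removing that set
shatters it into well-separated components. The removed vertices (the
*critical attack set* S) are the boundary population: candidate outliers or
samples genuinely intermediate between groups.

Three objectives quantify how badly a removal fragments a connected graph
G = (V, E), writing C_max(V−S) for the largest surviving component and
ω(V−S) for the number of surviving components:

| measure | objective over S | favors |
|---|---|---|
| vertex attack tolerance (VAT) | \|S\| / (\|V−S−C_max\| + 1), S ≠ ∅ | cheap attacks stranding many nodes outside the main component |
| normalized integrity | (\|S\| + C_max) / \|V\| | attacks leaving only small components |
| tenacity | (\|S\| + C_max) / ω(V−S) | attacks producing many components |

VAT requires a non-empty attack set; integrity and tenacity admit S = ∅ (and
integrity S = V, with C_max defined as 0). These conventions follow the
definitions of the minima, and the brute-force oracle enumerates exactly
those admissible subsets.

### Greedy-BC search

Exact minimization over subsets is exponential, so the search is restricted
to prefixes of a greedy removal order: repeatedly delete the vertex of
highest *weighted* betweenness centrality (edge weights are Euclidean
distances, i.e. path lengths), recomputing centralities after every deletion,
and score the objective after each one. The returned attack set is the prefix
with the minimal objective; ties prefer smaller prefixes, and betweenness
ties are broken toward the lowest node index so runs are reproducible. The
default removal budget is |V|−2 deletions (no principled stopping rule
exists; the full sweep is a superset of any truncation and keeps the search
deterministic). Betweenness and component extraction run through igraph's C
implementations; with the full budget the search costs |V| betweenness
computations, which keeps 400-node graphs in the seconds range.

The greedy objective is an upper bound on the true minimum; the test suite
verifies it never undershoots the brute-force optimum and that it attains the
optimum exactly on stars, paths, and two-clique barbells.

### From attack set to clusters

Surviving components become base clusters. Two output modes share one
underlying clustering of all of V:

1. the attack set is folded back in (*complete clustering*), and
2. the *no-reassignment* output is that same clustering restricted to V−S,
   with S reported as candidate outliers.

The fold-back is **iterated neighbor voting**: in rounds, every still-
unlabelled attack node adjacent to a labelled node joins the cluster winning
its labelled-neighbor vote (ties → larger cluster, then lower cluster id).
By default each neighbor votes with weight 1/distance. This weighting is
load-bearing, not cosmetic: on union-symmetrized kNN graphs at minimal
connectivity, the critical attack nodes are precisely the "gateway" points
that receive the overflow neighbor edges of smaller groups, so most of their
adjacency points *across* the boundary and a plain count vote systematically
hands them to the wrong cluster. Distance weighting restores the local
geometry (an attack node's own-group neighbors are near, the far side's
overflow edges are long). A plain count vote remains available
(`strategy="count"`); the two coincide on unit-weight graphs.

Reassignment happens *before* any merge/split adjustment, in both modes.
This ordering is forced by a structural fact: surviving components are often
connected only *through* the removed attack core, so the bare components can
have zero direct inter-cluster edges, which would blind the normalized-cut
merge entirely (every pair ties at 0). Folding the attack set back first
restores the edge signal; restricting afterwards gives the no-reassignment
view. A corollary is that the two modes agree exactly on the surviving nodes.

### Adjusting to a requested k

- **Too many clusters:** repeatedly merge the pair (C₁, C₂) maximizing the
  normalized cut E(C₁,C₂)/(|C₁|·|C₂|), where E counts inter-cluster edges in
  the full graph; ties go to the lexicographically smallest cluster-id pair.
- **Too few:** among clusters with ≥ 3 nodes, re-attack the one whose induced
  subgraph has the lowest greedy resilience value (the same measure as the
  top-level run, by default), replace it with its surviving sub-components
  (inner attack set reassigned), and repeat. A split that overshoots the
  requested k is walked back by normalized-cut merging. Clusters whose
  induced subgraph never disconnects under the greedy attack (e.g. near-
  cliques) are unsplittable; when none remain the operation reports the
  achievable k instead of fabricating clusters.

## Validation indices and selection

Nine internal validation indices are implemented directly from their
formulas; conventions that the formulas leave open are fixed as follows:

- **Silhouette** is macro-averaged: the mean over clusters of the cluster's
  mean s(x). Singletons (and points with max(a, b) = 0) contribute s(x) = 0.
  This differs from the common micro-average over points when cluster sizes
  are unequal.
- **Cluster scatter** σ(C_i) is the per-dimension *population* variance
  vector; its norm is Euclidean. `Scat(k)` is the mean ratio
  ||σ(C_i)|| / ||σ(D)||.
- **SD index** = Dis(k_max)·Scat(k) + Dis(k), where Dis(k_max) comes from the
  largest-k member of the family of configurations being compared.
- **S_Dbw** uses the density radius (1/k)Σ||σ(C_i)|| — a point is "within"
  a location if its distance does not exceed the average cluster
  standard-deviation norm.
- **I index** exponent defaults to p = 2.
- **CVNN** uses NN = 10 neighbors by default; its compactness term sums over
  clusters without dividing by k (as printed in its source formulation), and
  its separation/compactness terms are rescaled by the maxima over the
  compared family of configurations. Inside a grid run the "family" is the
  k-sweep within one (graph, measure, mode) cell; a configuration scored
  alone is its own family (CVNN then degenerates to a constant 2, which is
  harmless since selection only ever compares within families).

Two graph-quality measures gate admissibility: Newman modularity of the
partition (unweighted; threshold 0.6) and conductance in the
fraction-of-all-edges form — per cluster, the number of edges with exactly
one endpoint inside divided by the total edge count (threshold 0.07). The
gated statistic is the **maximum** over clusters (the worst cluster decides);
the mean is also reported. In no-reassignment mode both measures are
computed on the induced subgraph of assigned nodes, so attack-set edges do
not enter the tallies.

Selection: configurations whose smallest cluster falls below a size floor
(default fraction 10/2680 of the scored samples, scaling the absolute floor
of the motivating study) are discarded outright. Each of the nine indices
then casts one vote for the best surviving configuration in its optimal
direction (max for SI/CH/Dunn/I, min for DB/XB/SD/S_Dbw/CVNN). The gates act
as *secondary* criteria, not a vote pre-filter: ranking is by votes won, then
gate admissibility, then Silhouette. This matches how the selection behaves
in practice in the source framework, where chosen configurations can fail an
individual gate while dominating the index vote; a gate-failing
configuration still never outranks an admissible one with equal votes. Index
ties award the vote to the earliest configuration in input order
(deterministic).

## Preprocessing conventions

- **Mean imputation** per feature; an all-missing column is an error.
- **Regression imputation**: per target, an OLS model with intercept on all
  other features, fit on rows where the target is observed (predictor gaps
  mean-filled for the fit only); predictions are clipped to the feature's
  known score range when one is declared. A rank-deficient design falls back
  to mean imputation with a logged warning. Which features receive the
  regression treatment is the caller's choice.
- **Normalization** maps each feature to [0, 1] by its known score range,
  falling back (logged) to the observed min/max; constant columns map to 0;
  a declared range with max ≤ min is rejected.
- **Correlation filter**: while any pair exceeds the threshold in |Pearson
  r|, the most-correlated pair is found and the member with the larger mean
  absolute correlation to the remaining features is dropped (ties drop the
  later column). Zero-variance columns have undefined correlations, treated
  as 0 — they are never removed on that account.

## Graph construction conventions

The kNN relation is directed and symmetrized by **union** (an edge exists if
either endpoint lists the other among its k nearest); mutual-AND
symmetrization is available but does not share the union graph's
connectivity behavior, which the min-conn construction relies on. Distance
ties are broken by node index via a stable sort. *min-conn* is found by
binary search, valid because edge sets are nested in k and connectivity is
therefore monotone. The experiment grid's base graphs are built at
min-conn+{0,1,2} for each feature set (full and correlation-filtered) — the
connectivity-offset labels refer to these settings, not to literal k values.
Duplicate points are allowed and produce zero-weight edges; shortest-path
computations floor weights at 1e-12.

## Synthetic data: what it emulates and what it does not

The generator produces isotropic Gaussian mixtures with configurable cluster
count, center separation (in units of the within-cluster σ), uniform
bounding-box outliers (planted analogs of the attack set's "possible
outliers"), appended noisy-duplicate feature pairs (|r| > 0.9) for the
correlation filter, and uniformly random missing cells. A companion
`phenotype_like_table` emulates the *shape* of a clinical severity
inventory: 500 samples × 36 bounded score-range features in six instrument
groups, four planted severity subgroups driving ~half of each feature's
variance through a latent factor, exactly three near-duplicate features (so
the 0.8 filter removes three), and ~0.1% missing cells concentrated ≥ 90% in
two designated columns. Feature names and ranges are plausible-looking but
synthetic; they carry no clinical content.

Passing the benchmarks shows the pipeline recovers *well-separated,
isotropic, equally-dispersed* structure and that every formula is
implemented exactly. Real phenotype data is none of those things —
anisotropic, unevenly sized, heavy-tailed, with graded rather than separated
severity — so benchmark recovery rates do not transfer; the benchmarks
validate the machinery, not clinical performance.

Default fixture conditions used by the acceptance checks: n = 400, d = 5,
four planted clusters at 8σ separation, three seeds; the 500×36
phenotype-like table for the study-design counts. Problem sizes were chosen
so the whole acceptance run stays in the minutes range on one CPU.

## Known limitations

- The greedy search is a heuristic: no approximation guarantee, and on
  graphs whose clusters are near-cliques it cannot split them (correctly
  reported as unsplittable rather than silently mis-split).
- min-conn grows with cluster size for well-separated isotropic groups
  (every point's nearest neighbors are its own group), so dense kNN graphs —
  and O(|V|) betweenness recomputations on them — dominate the runtime for
  large n. Graphs beyond a few thousand nodes need a betweenness
  approximation, which is out of scope here.
- Overlapping or soft assignments are not produced; the attack set is the
  only "between clusters" signal.
- The conductance gate (0.07) and modularity gate (0.6) are absolute
  thresholds inherited from the motivating study; on graphs with very
  different edge densities they may gate everything in or out, which is why
  they rank rather than filter.
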