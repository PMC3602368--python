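# Methods

## Scope and object of study

`reservenet` analyses a protected-area system as a spatial graph for one
species at a time. The inputs are a per-species site table (site id,
planar centroid in km, habitat area in ha, current and future suitability
flags) and the species' median dispersal distance. Everything upstream of
that table — species distribution modelling, suitability thresholds, the
delineation of habitat area inside a site — is treated as given input, not
modelled here. Coordinates are assumed already projected; the package does
no geodesy.

## Graph construction

Sites suitable in the chosen epoch become nodes; an edge joins two nodes
when their distance is *less than or equal to* the dispersal distance
(inclusive comparison). Unsuitable sites are dropped entirely rather than
kept as zero-weight ghosts. Two distance modes exist:

- `centroid` — Euclidean centroid-to-centroid distance; default for the
  topology metrics.
- `edge_approx` — centroid distance minus the equivalent-circle radii
  √(area/π) of both sites, floored at 0; a patch-as-disc approximation of
  edge-to-edge distance, default for the habitat-weighted indices. True
  polygon distances are out of scope; a user-supplied distance matrix
  overrides either mode.

Using centroid distances for topology but edge-approximated distances for
the area-weighted indices mirrors standard practice in this index family,
where within-patch area already counts as connected area.

## Topology metrics

Degree, connected components (with orders, isolated nodes = order-1
components, largest/smallest/mean ± sd order), articulation points,
betweenness and clustering come from standard algorithms (networkx).

Two reporting decisions matter on fragmented graphs:

- **Betweenness normalization is global**, by (n−1)(n−2)/2 with n the whole
  graph's node count, not per component. A multi-component reserve network
  then yields a single comparable mean; pairs in different components
  simply contribute nothing. The lost-vs-retained comparisons are
  invariant to this choice as long as it is fixed.
- **Clustering of degree-<2 nodes is 0 and included in the mean**, keeping
  the network mean defined when isolated sites dominate.

The degree-distribution check fits Poisson(λ̂ = mean degree) and tests by
chi-square on binned counts, adjacent bins pooled until every expected
count is ≥ 5, upper tail folded into the last bin, dof = bins − 2. A
chi-square on pooled discrete bins was chosen over KS because the support
is discrete and λ is estimated. The fit is refused below 20 nodes and
declared undefined with fewer than 3 pooled bins (e.g. all degrees zero).
"Small components" in comparisons are those of order < 10.

## Habitat-weighted indices

The dispersal kernel is negative-exponential, p(d) = exp(−d·ln2/h). The
half distance h defaults to the species' median dispersal distance, so
p = 0.5 exactly at the median — the natural anchor when the only dispersal
statistic available is a median. h is the one tunable parameter of the
index family; larger h can never decrease ECA (tested property).

p\*ᵢⱼ is the maximum, over all chains of sites, of the product of per-step
probabilities, with **every** site pair as a candidate step (complete
graph) — any site can be a stepping stone regardless of the topological
threshold. Because −log p is proportional to distance, the computation is
a single metric shortest-path problem (Dijkstra on the dense distance
matrix), exact and kernel-independent up to the final exponential.

PC numerator = Σᵢⱼ aᵢaⱼp\*ᵢⱼ includes the diagonal (p\*ᵢᵢ = 1), which is
required for the single-patch identity ECA = a. ECA = √(PC numerator)
satisfies √(Σaᵢ²) ≤ ECA ≤ Σaᵢ with both bounds attained in the isolated
and fully connected limits; site removal can never increase the PC
numerator. These closed forms and monotonicities are tested exactly.

GBC(k) sums aᵢaⱼp\*ᵢⱼ over pairs {i, j} whose optimal path passes through
k, detected by L(i,k) + L(k,j) = L(i,j) on the optimal path lengths with a
1e-9 relative tie tolerance. **Tie rule:** when several optimal paths tie,
the pair contributes in full to every node on at least one of them. This
is deterministic and oracle-checkable; collinear site geometries (where a
through-path product exactly equals the direct probability) exercise it.

Scenario change is summarized by dA = 100·(A_fut − A_cur)/A_cur and
dECA = 100·(ECA_fut − ECA_cur)/ECA_cur; dECA > dA flags an impact on
connectivity weaker than proportional to the habitat loss. Reported
percentages are rounded half-up to 2 decimals; internal values keep full
precision.

## Scenario accounting

Only range contraction is modelled: a site suitable in the future but not
currently is ignored. This is the conservative choice — colonization of
new sites is far less certain than loss — and it makes the future graph an
induced subgraph of the current one (a tested invariant). A current
component counts as *lost* when none of its nodes persist, and as *split*
when its survivors fall into more than one future component.

## Statistical layer

The headline test is a Monte-Carlo permutation test of
mean(lost) − mean(retained) for a node metric: the null is built from
n_perm (default 999) subsets of size |lost| drawn without replacement from
the pooled current nodes, with p = (1 + #as-or-more-extreme)/(n_perm + 1).
The +1 smoothing keeps p ≥ 1/(n_perm+1) and makes the test valid at finite
n_perm. Sidedness defaults to two-sided; a zero-variance pool returns
p = 1. Every stochastic routine takes an explicit seed.

Mann–Whitney U (reported as min(U_a, U_b), midrank ties, exact null when
n_a·n_b ≤ 400 and tie-free, otherwise normal approximation with tie
correction) covers the clustering-coefficient and component-order
comparisons; Spearman's ρ (midranks, t-approximation) relates losses per
component to component order. No multiple-testing correction is applied
across metrics or species.

## Synthetic data generator

The generator emulates the structure this analysis assumes: cluster
centers rejection-sampled ≥ `inter_cluster_km` apart in a square arena of
side 6·inter_cluster_km·√n_clusters (which keeps rejection sampling
tractable at any cluster count), Gaussian within-cluster scatter,
log-normal areas, and loss probability ∝ exp(−degree_bias·degree) scaled —
by bisection on the proportionality constant, with capping at 1 — so the
expected loss fraction equals `loss_rate`.

Defaults are fixed study conditions: 8 clusters × 25 sites (≈200 sites),
spread 30 km, spacing 300 km, log-area μ = 9.5, σ = 1.0 (median ≈13 kha,
mean ≈22 kha — the order of magnitude of large European protected sites),
loss_rate 0.15, degree_bias 2, dispersal 90 km. With bias 0 losses are
exchangeable (used to check permutation-test calibration); with bias 2 the
lost-sites-are-less-connected signature is recovered.

What the generator does **not** emulate: real site geometry and polygon
adjacency, spatially autocorrelated climate impacts (losses are
independent given degree), area–suitability correlation, and colonization.
Passing tests therefore demonstrate correctness and statistical behaviour
of the pipeline under the assumed structure, not fidelity to any real
reserve system.

## Problem sizes and numerics

Test and acceptance runs use networks of ~200 sites (the calibration
suites), brute-force oracle comparisons on graphs of ≤ 12 nodes (≤ 8 for
factorial-cost path enumeration), 1000 replicates at n_perm = 199 for
type-I-error calibration, and 100 seeds for the signature-recovery and
degree-law checks — sizes at which exhaustive oracles are feasible and the
whole suite runs in well under a minute. ECA closed forms are asserted to
1e-9; path-length ties use a 1e-9 relative tolerance; percentage rounding
is half-up at 2 decimals.

## Known limitations

- The patch-as-disc edge distance underestimates distances between
  elongated sites and can reach 0 for overlapping discs.
- Global betweenness normalization makes per-node values depend on total
  network size; compare within a network, not across networks.
- The permutation test assumes exchangeability under the null across the
  whole node pool; strong spatial clustering of losses for reasons other
  than the measured metric would violate it.
- Dense all-pairs shortest paths cost O(n²·log n)–O(n³); networks beyond a
  few thousand sites need sparsification upstream.
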