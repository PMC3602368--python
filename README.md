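# reservenet

Graph-theoretic assessment of how well a protected-area network stays
connected for a species when climate and land-use change make some of its
sites unsuitable.

**Who it is for.** Conservation and landscape ecologists who have, per
species, a table of protected sites (centroid, habitat area, current and
projected future suitability) and a dispersal distance, and who want to know
whether the sites predicted to be lost are a random sample of the network or
a biased one — and how much connectivity the network loses relative to the
habitat area it loses.

## The model

Each protected site is a node at its centroid (planar coordinates, km) with
habitat area *aᵢ* (ha). Two sites are linked when their distance *d* is at
most the species' median dispersal distance *D* (an edge iff *d ≤ D*). On
this dispersal-threshold graph the package computes the classical topology
suite — node degree, components and their orders, isolated nodes,
articulation (cut) points, betweenness centrality *BC*, clustering
coefficient *C*, and a Poisson goodness-of-fit test on the degree
distribution (Poisson degrees indicate a random rather than scale-free
network).

Habitat-weighted connectivity uses the probability-of-connectivity family.
A negative-exponential dispersal kernel *p(d) = exp(−d·ln2/D)* (so
*p(D) = 0.5* at the median dispersal distance) gives each pair of sites a
maximum product-of-steps probability *p\*ᵢⱼ* over all stepping-stone chains,
computed exactly as a shortest path on −log *p*. From these:

- **PC numerator** = Σᵢ Σⱼ aᵢ·aⱼ·p\*ᵢⱼ (ha², including *i = j*);
- **ECA** (Equivalent Connected Area) = √(PC numerator), the size of the
  single patch with the same connectivity value; ECA ranges from
  √(Σaᵢ²) (all sites isolated) to Σaᵢ (all perfectly connected);
- **GBC** (Generalized Betweenness Centrality) of node *k*: the sum of
  aᵢ·aⱼ·p\*ᵢⱼ over pairs whose optimal path passes through *k*.

A future scenario is pure range contraction: sites flagged unsuitable in the
future are removed, and the comparison reports node losses, components lost
or split, **dA** = %Δ habitat area, **dECA** = %Δ ECA (dECA > dA means the
network lost less connectivity than its area loss alone predicts), and
resampling tests (999-permutation subset test, Mann–Whitney U, Spearman) of
whether lost sites have lower degree, betweenness and GBC than retained
ones.

A synthetic-network generator (clustered site placement, log-normal areas,
loss probability ∝ exp(−bias·degree)) provides study-condition data for all
of this without any external download.

## Worked example

The built-in 12-site fixture has three components (orders 7, 4 and 1), one
articulation point (`a4`), and loses two sites (`a1` and the isolated `c1`)
in the future scenario:

```python
from reservenet import worked_fixture, compare_scenarios

cmp_ = compare_scenarios(worked_fixture(), dispersal_km=10.0, n_perm=999, seed=1)
report = cmp_.to_dict()
print(report["nodes"])
print(report["components"]["current"]["orders"], report["components"]["components_lost"])
print(report["indices"]["dA_pct"], report["indices"]["dECA_pct"],
      report["indices"]["weaker_impact"])
```

prints

```
{'current': 12, 'future': 10, 'losses': 2, 'pct_lost': 16.67}
[7, 4, 1] 1
-35.03 -23.94 True
```

Reading this: 2 of 12 sites (16.67%) are lost, one of them an entire
(isolated) component. Habitat area drops 35.03% but ECA only 23.94% — the
losses sit at the network's margin, so connectivity degrades less than
area (dECA > dA, `weaker_impact`). The current-epoch ECA is 904.6 ha
against 1770 ha of total habitat.

The same pipeline runs from the shell:

```
reservenet simulate --n-clusters 8 --sites-per-cluster 25 --seed 1 --out sites.csv
reservenet scenario-compare --sites sites.csv --dispersal-km 90 --seed 1 \
    --out-dir out --json
```

which writes node-metric CSVs, edge lists, GBC, and `comparison.json`
under `out/`.

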