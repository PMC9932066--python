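# pollinet

Quantitative plant–pollinator network analysis for multi-site field
studies, built around the workflow used in urban-ecology pollination
research: visitation records from repeated transect walks at sites along an
urbanisation gradient are turned into quantitative bipartite networks,
structural metrics are standardised against fixed-margin null models, and
site-level responses are related to landscape and local-habitat predictors.

## What it computes

For each site's plant × visitor visit-count matrix `a` (total `m`, row
totals `r_i`, column totals `c_j`):

* **Connectance** — realised links / (R·C).
* **NODF** — nestedness by overlap and decreasing fill on the binarised
  matrix (0–100): a row or column pair with strictly decreasing fill
  contributes `100 · shared presences / smaller fill`, equal fills
  contribute 0.
* **H2′** — network specialisation: the two-dimensional Shannon entropy of
  `p_ij = a_ij/m` standardised between the minimum and maximum entropy
  attainable by an *integer* table with the observed margins (0 fully
  generalised, 1 fully specialised).
* **d′** — visitor specialisation: the Kullback–Leibler divergence between
  a visitor's use of plants and plant availability `q_i = r_i/m`,
  standardised between its margin-constrained extremes; network-level d′ is
  the unweighted mean over visitor species.
* **Modularity Q** — Barber's weighted bipartite modularity
  `Q = (1/m) Σ_ij [a_ij − r_i c_j/m] δ(g_i, g_j)`, maximised by simulated
  annealing over joint plant/visitor module assignments.
* **Δ-transformation** — each metric minus its mean over random tables with
  exactly the observed margins (Patefield's algorithm; 1000 draws by
  default, 100 for modularity), removing the strong size-dependence of raw
  metrics.
* **3D connectivity** — Hanski's incidence-function index
  `S_i = Σ_j exp(−α·(d_ij + λ·H_ij))·A_j`, where `H_ij` sums building
  heights in a 25 m corridor around the route between patches: taller built
  corridors act as longer effective distances.
* **Scale of effect** — for each biological response, the buffer radius
  (100/500/1000 m) at which impervious surface correlates most strongly
  (largest |Pearson r|).
* **Community & regression stages** — Shannon diversity, minimum-visit
  filtering, square-root + Wisconsin double standardisation + Bray–Curtis,
  permutation-based environmental vector fitting on an ordination; VIF
  screening (cutoff 3), Poisson → negative-binomial count models, bounded
  all-subsets AIC selection (≤ 3 predictors), Moran's I residual
  diagnostics.

A first-class synthetic-data generator emulates the study design (11 dry
grassland sites, ~105 bee / 38 hoverfly / 22 butterfly species plus honey
bees, 8 sampling rounds, group-specific responses to urbanisation), so the
entire pipeline is testable end to end without field data.

## Worked example

```python
import numpy as np
from pollinet import (SyntheticConfig, build_network, delta_transform,
                      h2prime, modularity, nodf)
from pollinet.synthetic_data import generate_dataset

cfg = SyntheticConfig(seed=3)           # 11 sites, default species pools
landscape, records, predictors = generate_dataset(cfg)

net = build_network(records, "site_01")
print(net.shape, net.m)                  # (28, 26) 207

print(round(nodf(net), 2))               # 33.08
print(round(h2prime(net), 3))            # 0.221
q, partition = modularity(net, seed=0)
print(round(q, 3))                       # 0.37

d = delta_transform(net, "connectance", n_null=200, rng=1)
print(round(d.observed, 3), round(d.delta, 3))   # 0.146 -0.031
```

The site's network occupies 15% of its possible links, is moderately
specialised (H2′ ≈ 0.22), and splits into trait-matched modules
(Q ≈ 0.37).  Its Δ-connectance is negative: the observed network is
sparser than random tables with the same margins, the typical signature of
niche partitioning.

The same analysis runs from the shell:

```sh
pollinet simulate --seed 3 --out data/
pollinet run-all --seed 3 --out results/ --n-null 200 --n-null-modularity 60
```

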