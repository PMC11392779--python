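# divgrid

Gridded multi-dimensional biodiversity surfaces — taxonomic, functional and
phylogenetic diversity and endemism — and maps of their spatial congruence
and mismatch, for floras sampled as point occurrence records along an
environmental gradient.

## Who this is for

Biogeographers and spatial ecologists who have (i) species occurrence
points, (ii) a mixed-type functional trait table with per-trait importance
weights, and (iii) a dated phylogeny, and who want to know not only *where*
diversity and endemism concentrate but *where the different dimensions
disagree* — the residual mismatches that point at eco-evolutionary
mechanisms such as environmental filtering, recent in-situ radiations,
biotic exchange and geographic isolation.

## The metrics

For each grid cell *c* with species set *S(c)*:

- **TD** — species richness, |S(c)|.
- **WE** — weighted endemism, Σ_{s∈S(c)} 1/|range_s|, with |range_s| the
  number of cells the species occupies.
- **PD** — Faith-style phylogenetic diversity: the sum of branch lengths
  L_b of the tree subtree spanning S(c) (root path included by default,
  MRCA-rooted available).
- **PE** — phylogenetic endemism: Σ_b L_b / |r_b| over the same branches,
  where |r_b| is the number of cells holding any descendant of branch *b*.
- **FD / FE** — the same two branch sums evaluated on a functional
  dendrogram: weighted Gower similarity over mixed-type traits
  (S_ij = Σ_k w_k δ_ijk s_ijk / Σ_k w_k δ_ijk), converted to D = 1 − S and
  clustered by UPGMA.

The working grid resolution is chosen by sampling redundancy,
1 − richness/samples per cell: the finest candidate resolution whose
average redundancy over occupied cells reaches 0.6 is retained, and
low-redundancy cells are filled by inverse-distance-squared interpolation
within a 2-cell neighborhood.

Congruence between surfaces is mapped with geographically weighted
regression (GWR, and a multiscale variant with per-term bandwidths): at
each cell, a weighted least-squares fit with Gaussian kernel weights
w_ij = exp(−½ (d_ij/b)²), the bandwidth *b* selected by golden-section
search on the corrected Akaike criterion
AICc = 2n ln σ̂ + n ln 2π + n(n + tr(S))/(n − 2 − tr(S)).
Six model pairs are fitted (FD~TD, PD~TD, FD~PD, WE~FE, WE~PE, FE~PE);
signed residuals mark cells where the response exceeds (positive) or falls
short of (negative) the value expected from the predictor.

A synthetic-data module generates occurrence/trait/tree worlds with the
statistical structure each mechanism predicts (five named scenarios), so
the whole pipeline is testable end to end without any data download.

## Worked example

Generate an environmental-filter world (arid-adapted species converge in
trait space), build all six surfaces and ask whether functional diversity
in arid cells falls below what richness predicts:

```python
import numpy as np
import divgrid as dg

cfg = dg.ScenarioConfig(scenario_name="environmental_filter", seed=7)
world = dg.generate_world(cfg)

pm = dg.assign_to_cells(world.occurrences, world.grid)
dendro = dg.upgma(dg.gower_dissimilarity(world.traits))
surfaces = dg.compute_all_surfaces(pm, world.tree, dendro)

suite = dg.run_model_suite(surfaces, models=(("FD", "TD"),))
res = suite["FD~TD"]["result"]
print(res.summary())
arid = world.cell_aridity()[suite["FD~TD"]["cells"]] > 0.7
print(f"median FD~TD residual, arid cells:  {np.median(res.resid[arid]):+.4f}")
print(f"median FD~TD residual, mesic cells: {np.median(res.resid[~arid]):+.4f}")
```

prints

```
============================================================
Geographically weighted regression: FD~TD
------------------------------------------------------------
No. observations:                    329
Bandwidth:                         28.74
Effective parameters tr(S):       80.336
Residual sum of squares:          0.4319
AICc:                         -1032.4586
Local R2 (min/median/max):     0.033   0.940   0.994
Converged:                          True
------------------------------------------------------------
median FD~TD residual, arid cells:  -0.0013
median FD~TD residual, mesic cells: +0.0019
```

The negative arid-cell median is the environmental-filter signature:
functional diversity in the arid zone is lower than its richness predicts,
while mesic cells sit on or above the locally expected relationship.

There is also a thin CLI (`divgrid simulate`, `divgrid all --config
cfg.yaml`, `divgrid report --table species.csv --by family`) over the same
library calls.

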