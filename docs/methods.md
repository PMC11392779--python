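# Methods

This note records the models, conventions and design choices behind
divgrid, in the order the pipeline applies them.

## Gridding and resolution selection

Occurrence records are planar points (the package expects projected
coordinates; a latitude/longitude dataset must be projected first — grid
cells are squares in map units, and mixing geographic degrees with
kilometre cells is not meaningful). Cells are half-open intervals
[lo, hi) indexed row-major from the grid origin, so a point exactly on a
boundary belongs to the higher-index cell; the convention is arbitrary but
deterministic, which is what reproducibility needs. An optional per-species
bounding-box filter removes out-of-range records (with a drop log) before
gridding.

Sampling completeness per cell is *redundancy*, 1 − richness/samples:
zero means every species in the cell was recorded exactly once (no
evidence the inventory is complete), values approaching one mean heavy
resampling. The working resolution is selected among candidate cell sizes
(default 25/50/75/100 in map units) as the finest whose average redundancy
over occupied cells (ARd) reaches 0.6; if none qualifies the best
available is used and flagged. Empty cells are excluded from ARd — they
carry no information about sampling effort. Both the candidate list and
the threshold are configuration.

Cells below the redundancy threshold have their six metric values replaced
by an inverse-distance-squared weighted mean of above-threshold cells
within a Chebyshev radius of 2 cells (both the radius and the weight use
Chebyshev distance in cell units). IDW was chosen over geostatistical
(kriging-type) interpolation deliberately: it is deterministic, free of
variogram choices the data cannot support at these cell counts, and its
convexity (filled values lie within the range of contributing neighbors)
is a testable contract. The interpolator is pluggable for users who want
something richer; cells with no qualifying neighbor stay missing rather
than being filled from nothing, and original values are retained in a log.

## Branch-length metrics

One engine serves the phylogeny and the functional dendrogram. For a cell
with species set S, *branch-sum diversity* is the total length of the
subtree spanning S. Two rooting conventions are exposed because usage in
the literature is genuinely split: `root` (default) includes the path from
the spanning subtree's MRCA to the tree root — the classical Faith
convention, under which a singleton cell still carries its full lineage
depth — and `mrca` truncates at the MRCA. All package-level invariants
(endemism ≤ diversity, monotonicity under species addition, conservation)
hold under either.

*Range-weighted endemism* divides each branch length by the branch's
range, the number of cells containing at least one descendant of that
branch, and sums over the same spanning branches. Under the `root`
convention this yields an exact conservation law — summed over all cells,
endemism equals the total length of the subtree spanning all occurring
species — which the tests exploit as an oracle on random fixtures. Branch
ranges are cell counts; an optional flag divides by the total number of
cells instead (some published endemism values are normalized per unit
area), off by default.

Species present in the data but absent from the tree can be grafted at
genus level: a species whose genus has two or more tips is attached as an
extra child of the genus MRCA with pendant length equal to the mean tip
depth below that node (a polytomy; ultrametric trees stay ultrametric),
and a species whose genus has a single tip splits that tip's pendant
branch at its midpoint. Species whose genus is absent are dropped and
logged. This is a deliberately simple, deterministic placement rule; it
does not attempt the randomized or dated placements of full tree-grafting
toolkits.

## Functional dendrogram

Mixed-type traits are compared with the weighted Gower similarity
S_ij = Σ_k w_k δ_ijk s_ijk / Σ_k w_k δ_ijk, where δ marks the trait being
observed in both species, s_ijk is an equality indicator for binary and
categorical traits and a range-normalized linear similarity for continuous
traits, and w_k ∈ [0, 1] is the trait's importance weight. Ordinal traits
are rank-scaled first and then treated as continuous (Gower's
rank-normalized distance); continuous ranges are taken over the full
species pool, not per cell, so that a single global dendrogram describes
every cell. A species pair sharing no positively weighted observed trait
is a hard error — silent imputation would manufacture similarity.

The dendrogram is UPGMA (unweighted pair-group average linkage) on
D = 1 − S, with node heights equal to half the merging average
dissimilarity; ties are broken by the lexicographically smallest pair of
cluster representatives so output is identical across platforms. The
implementation is the package's own (the tie-break rule and the
tree-object output are not served by library linkage routines); scipy's
average linkage is used in the test suite as an independent cross-check on
tie-free inputs, alongside a brute-force O(n³) agglomeration oracle.

FD and FE are then the two branch sums evaluated on this dendrogram, with
the same mode flag as PD/PE.

## Geographically weighted regression

GWR fits, at every cell centroid i, weighted least squares of y on [1, x]
with Gaussian kernel weights w_ij = exp(−½ (d_ij/b)²) and a fixed distance
bandwidth b (an adaptive nearest-neighbor bandwidth is deliberately not
the default anywhere). Per-location solutions use the closed-form 2×2
normal equations evaluated for all locations simultaneously; a location
whose weighted predictor carries no variance is flagged degenerate (slope
0, weighted-mean intercept) rather than crashing the surface. Local R² is
geographically weighted: 1 − RSS_w(i)/TSS_w(i) with the same kernel row,
so it is bounded in [0, 1].

The bandwidth minimizes the corrected Akaike criterion
AICc = 2n ln σ̂ + n ln 2π + n (n + tr(S)) / (n − 2 − tr(S)), σ̂² = RSS/n,
with tr(S) the hat-matrix trace, via golden-section search on a default
interval [minimum non-zero inter-point distance, extent diagonal] and
relative tolerance 1e-3. Bandwidths at which tr(S) ≥ n − 2 are
inadmissible and rejected inside the search.

The multiscale variant (MGWR) gives each term (intercept, slope) its own
bandwidth by backfitting on partial residuals, initialized from the
single-bandwidth GWR fit, with term bandwidths re-selected by
golden-section AICc each sweep and convergence declared when the change in
fitted values (SOC-RSS) falls below 1e-5 (cap 200 iterations;
non-convergence is reported on the result, not raised). With all
bandwidths constrained equal, MGWR is by definition ordinary GWR at that
bandwidth and is solved jointly rather than iterated.

Six response~predictor pairs are fitted (FD~TD, PD~TD, FD~PD, WE~FE,
WE~PE, FE~PE) on cell centroids; cells missing either variable are
excluded, interpolated cells included. Residual signs (positive: response
above the locally expected value; negative: below; neutral within a
configurable ±ε band, default ε = 0) are the mismatch map.

## Synthetic worlds

The generator emulates the statistical structure of a regional flora
sampled along an aridity gradient, not any particular place: a monotone
aridity gradient with smooth spatial noise (amplitude 0.2 of the unit
range — aridity is patchy at fine scale, as topography makes it in real
systems; with amplitude 0 the gradient is strictly monotone), a pure-birth
ultrametric phylogeny (expected root depth Σ_{k=2..n} 1/(k·birth rate),
which the tests verify by Monte Carlo), and 11 traits evolved as Brownian
motion on the tree — six continuous, three ordinal (latents cut at
quartiles) and two binary (cut at the median), with configurable weights.

Species ranges are contiguous niche bands: each species draws an aridity
optimum and occupies the cells closest (in Chebyshev distance from a
maximally suitable center cell) among those within its niche breadth
(0.15 aridity units), up to a Poisson-distributed target range size (mean
8 cells), thinned by a Bernoulli false-absence filter (rate 0.5 — real
occurrence data miss many occupied cells, and without this the synthetic
surfaces are so smooth that AICc selects a one-cell bandwidth and local
fits absorb every zone-level signal). The center cell is always kept, so
no species ends up rangeless. Sampling effort per occupied cell is uniform
on 1–5 records.

Five scenarios impose the signatures the congruence analysis is meant to
detect:

- **congruent** — optima are mesic-skewed (Beta(1.5, 3)); richness, PD and
  FD all track moisture with no built-in mismatch.
- **environmental_filter** — optima uniform; species with optimum above
  aridity 0.7 have their trait latents shrunk toward the common ancestral
  state by `filter_strength` (default 0.9). The shrink applies to the
  latents behind the discrete traits as well as to the continuous traits:
  the mechanism being emulated restricts the whole trait space, and
  convergence limited to a subset of traits leaves the dendrogram's fine
  structure dominated by the unconverged ones.
- **in_situ_radiation** — half the species form a star-like clade with
  crown age 3% of tree height, niche optima in the hyper-arid extreme
  [0.85, 1] and range widths scaled by 0.35 (neoendemics are
  narrow-ranged); background taxa thin out above aridity 0.85, so clade
  dominance — and the PD deficit — grows smoothly across the arid band.
- **biotic_exchange** — the most evolutionarily distinct lineages (longest
  pendant branches) concentrate in the transition band (aridity 0.4–0.7),
  raising PD relative to TD there.
- **isolation_endemism** — a configurable fraction of species (default
  0.5) is restricted to a single cell; at fraction 1, WE equals TD in
  every cell exactly, which the tests assert.

All randomness flows from one seed; identical configurations produce
bit-identical worlds, files included.

### What the generator does not emulate

Real climate fields (aridity is one scalar standing in for the
precipitation/elevation interplay), mechanistic dispersal, taxonomic error,
spatially biased collecting (roads, herbaria), or abundance. Passing
recovery tests therefore show that the pipeline detects the designed
statistical signatures at realistic noise levels — not that any particular
real flora exhibits them.

## Problem sizes and numerical choices

The standard synthetic conditions used throughout the tests are 20×20
grids of 25-unit cells with 200 species, 20 replicate worlds per scenario;
metric conservation laws are checked on 100 random fixtures of up to 50
species and 100 cells, and UPGMA against its brute-force oracle on 50
matrices of up to 12 species. GWR oracles use fixtures of 25–30 locations
where brute-force per-location solves are exact to machine precision.
Golden-section tolerance 1e-3 (relative), MGWR SOC-RSS tolerance 1e-5,
UPGMA tie tolerance exact-equality on the minimum, ultrametricity asserted
at 1e-9 relative leaf-depth spread. Degenerate inputs are contracts, not
crashes: empty cells are NaN (never zero-filled), singleton leaf sets have
MRCA-mode diversity 0, incomparable trait pairs and empty search intervals
raise typed errors.

## Known limitations

Grafting is genus-level and deterministic only; the MGWR backfitting
variant is one of several in circulation and equivalence is claimed only
to the algorithm stated here; PE/FE absolute scales depend on the range
normalization convention (cell counts by default); and the composition
summary's half-up percentage rounding is a choice — count ratios sitting
exactly on a rounding boundary differ under other rules.
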