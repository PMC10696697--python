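# Methods

This note documents the model implemented by `diverscale`, the
conventions and numerical choices behind it, what the synthetic study
landscape does and does not emulate, and the package's known
limitations. It states no empirical result that the test suite and
`scripts/acceptance.py` do not themselves compute.

## Model overview and assumptions

One simulation follows a single clade on a gridded, time-varying
seascape. All processes act at the population level; species-level
pattern is emergent. The core assumptions:

- **Abundance is a proxy.** Per-cell abundance lives in [0, 1]; there is
  no explicit demography, age structure, or within-cell genetics.
- **Divergence is an abstract clock.** Pairwise divergence between
  populations is a counter in timesteps (+1 without gene flow, −1 with,
  floored at 0), a stand-in for the accumulation and erosion of genetic
  incompatibilities. Speciation is strictly allopatric: a group of
  populations speciates when its divergence to every remaining
  population of the species exceeds the threshold ρ. There is no
  sympatric speciation, introgression, or horizontal transfer.
- **Habitat is binary.** A cell is habitable iff marine, mean
  temperature ≥ 17 °C, and depth ≤ 2000 m (warm shallow reef habitat);
  outside that it contributes only as passable (sea) or impassable
  (land) space for dispersal.
- **Timestep duration is metadata.** All thresholds are in timesteps;
  the package never converts them to absolute time (the nominal
  duration attached to a landscape is carried but unused).

## Biological parameters

Six parameters vary between simulations; Sobol sweeps draw them from
the ranges below (defaults are the midpoints).

| parameter | meaning | range | default |
|---|---|---|---|
| `initial_abundance` | abundance of a freshly colonised cell (incumbency) | 0.11–1 | 0.555 |
| `thermal_optimum` | root species' optimum, °C | 17–31.4 | 24.2 |
| `dispersal_scale` | Weibull kernel scale, km | 100–5000 | 2550 |
| `speciation_threshold` | ρ, timesteps of divergence | 12–600 | 306 |
| `mutation_sd` | per-step trait mutation s.d. | 0.01–0.15 | 0.08 |
| `niche_width` | competitive half-width *w* | 0.02–0.50 | 0.26 |

The Weibull shape is fixed at 2.5. The thermal response s.d. (2 °C),
the local-extinction threshold (0.1), and the habitability cut-offs are
model constants, not swept.

## Per-timestep loop and its conventions

Order: housekeeping → speciation → dispersal → trait evolution →
ecology. Divergence is updated with the *previous* step's gene-flow
record, so a pair of populations isolated from the start first exceeds
ρ — and speciates — at timestep ρ + 1.

**Populations (geographic clusters).** A species' populations are
connected components of its occupied cells under 8-adjacency, with
components fused when the minimum cost distance between them is below
the 99th percentile of the species' dispersal kernel
(scale · ln(100)^(1/shape) ≈ 1.84 · scale). A population is thus a
dispersal-connected patch system, not merely a block of adjacent cells.
Clusters are recomputed every step for the current coastline.

**Divergence bookkeeping under topology change.** When clusters merge,
divergences to third parties are occupancy-weighted means of the
predecessors'; fragments of a single former cluster restart at mutual
divergence 0. Because merges average integer counters, stored
divergences are floats. The gene-flow record crosses the recompute via
the old-to-new cluster mapping (a recorded pair links all fragment
pairs of its two old clusters). Gene flow decrements a pair once per
timestep regardless of how many cell-level successes linked it, keeping
divergence in units of timesteps; flow in either direction counts.

**Speciation partition.** Components of the graph on cluster pairs with
divergence ≤ ρ. The component with the most occupied cells keeps the
parent identity (ties: lowest cluster index). Several children can
arise in one step; each logged event records the smallest
cross-component divergence, which is provably > ρ.

**Dispersal.** One Weibull draw per (source cell, habitable target
cell) pair, in ascending species-id order with a fixed array layout, so
a single seeded generator makes runs bit-reproducible. A colonised cell
takes the source cell's traits (not the cluster mean) and joins the
source's cluster; if several sources succeed in one step the
lowest-indexed one wins and later successes are ignored for that step.

**Trait evolution.** Independent Normal(0, σ) increments per occupied
cell on both traits, then cluster-mean homogenisation; the competitive
niche is clamped to [0, 1] after homogenisation.

**Ecology.** Abundance starts each step at 1 — except cells colonised
this step, which start at `initial_abundance` (this is what makes the
parameter matter: an incumbent meets competition at full abundance, a
coloniser does not). The thermal multiplier is the Gaussian density
ratio normalised to 1 at the optimum, exp(−ΔT²/8); an unnormalised
density would extinguish even perfectly adapted lone species under the
0.1 rule. Competition removes
min(1, Σ_j a_j · overlap(i, j) / (2w)) of species i's abundance, where
overlap is the intersection length of the two niche intervals
[niche − w, niche + w]: the 1/(2w) constant makes an identical-niche
pair at abundance 1 a full competitive load, and is isolated in one
place for substitution. Abundances update simultaneously from the
post-thermal values. The boundary penalty multiplies by
1 − outside/(2w), with `outside` the niche-interval length beyond
[0, 1]. Cells below 0.1 are vacated; empty species are marked extinct.

## Landscapes

Synthetic worlds are planar (cell size in km, diagonal steps cost √2 ×
cell size); sphericity is irrelevant to the mechanisms under study, and
a user-supplied distance function can replace the built-in one. Cost
distances are least-cost 8-neighbour paths through marine cells
(conductance 1) around land (conductance 0), computed with Dijkstra's
algorithm on a sparse graph and cached per unique coastline; pairs with
no sea route are infinite. Bioregions are contiguous longitudinal
blocks (five by default, echoing the five tropical realms) so that
β-diversity has a fixed regional partition without real geography.
Generated worlds combine a smoothed random elevation field (thresholded
to a land fraction), a latitudinal temperature gradient with smooth
spatial anomalies, sinusoidal sea-level cycles and temperature drift —
enough dynamics for isolation and reconnection events to occur.

Real climate keyframes can be densified with `preprocess_climate`:
focal moving-average smoothing (81-cell window by default) with polar
rows padded at −20 °C and longitude wrapping, then linear interpolation
in time, with no extrapolation beyond the keyframes. Smoothing and
linear interpolation commute, so the order does not matter.

## The study landscape (`make_multi_island_world`)

Scaled-down parameter sweeps run on a deterministic 20 × 20 archipelago
(500 km cells, 431 timesteps): sixteen Gaussian reef banks, four per
quadrant, with quadrant-specific spacings and sizes; a land cross whose
horizontal arm is permanent and whose vertical arm floods for a single
step at each 40-step sea-level peak; a latitudinal temperature field
with a 60-step drift. Rationale:

- The explored dispersal range (100–5000 km) spans the entire
  desk-scale domain, whereas in a global ocean even the largest kernels
  face basin-scale isolation. The permanent hemispheric barrier stands
  in for that missing extent, so between-hemisphere divergence accrues
  at every dispersal scale and the speciation threshold, not domain
  size, decides speciation.
- Brief east–west reconnections let dispersal ability modulate gene
  flow, recolonisation, and cluster merging without homogenising the
  whole world each cycle.
- Heterogeneous bank sizes and gaps keep some pair of banks in the
  intermediate gene-flow regime for any kernel scale, so sub-threshold
  population structure (the population-level diversity) exists across
  the sweep rather than at one knife-edge scale.
- Bank pairs within a quadrant share a latitude, so thermal filtering
  selects among quadrants, not within the population structure.

Ensembles on this world use 50 Sobol draws and retain every surviving
run: the published ≥ 20-extant-species retention rule is calibrated to
global-scale ensembles, and at this extent nearly all runs hold fewer
species (the rule itself, boundary-inclusive at 20, is unit-tested and
is the default of `run_ensemble_and_filter`). These sizes keep a full
sweep under a minute on one CPU.

What the study world does **not** emulate: real coastlines or the
actual shapes of the five realms, ocean currents and barriers (e.g.
cold-water upwelling), depth-graded habitat quality, or the sheer
extent of a global ocean. Passing tests on it show that the mechanisms
— threshold speciation partitioning diversity between levels, gene flow
eroding divergence, geography structuring β-diversity — behave as
designed; they do not show that effect *magnitudes* transfer to
real-world or global-scale configurations.

## Phylogenies and metrics

**Species trees** are built from the event log: each speciation is a
split at its event time, tips run to extinction or to the end of the
simulation, and the root keeps its stem, so a no-speciation run has
total length equal to the simulation duration and extant-only trees are
ultrametric. An alternative dating (`date_by="divergence"`) back-dates
each split by the divergence the separating populations had accrued;
under that convention the summed branch length across the two
organisational levels is conserved through a speciation event (up to
the event's own unit step), which is the formal content of the
diversity-partitioning argument. Event dating is the default and is
what all metrics use.

**Population dendrograms** come from complete-linkage agglomeration of
the cluster divergence matrix (the linkage is a parameter; complete is
the conventional default of the underlying toolchain). A merge at
height h puts its leaves at depth h/2, so cophenetic distance equals
divergence and a two-population dendrogram at divergence d has total
length d. No stem edge is added: a single-population species
contributes 0 to population PD and is excluded from population MPD
averaging. Per-simulation population-level PD/MPD are means across
species.

**Continuity** min–max normalises each constituent metric across the
ensemble (per metric, per level); normalised zeros are lifted to half
the smallest positive value so the log-ratio stays finite while
preserving order; a metric constant across the ensemble is an error
naming the metric. **β-diversity** is the mean pairwise distance of a
metric across bioregions (undefined with fewer than two defined
regions); it is computed per level and facet from the regional raw
values, which is what the level-vs-level β comparisons use.

**Clade properties.** Turnover = extant/(extant + extinct).
Weighted endemism uses the count-over-summed-ranges form per occupied
cell (the classical Σ 1/range form is available behind a flag).
Diversification rate is the mean over species of the reciprocal of
fair-proportions evolutionary distinctiveness. Trait evenness is a
normalised Camargo index on nearest-neighbour spacings (1 for even or
degenerate spacing); trait diversity is the mean absolute deviation.
Both are deliberately simple, documented, and swappable, since no
canonical formula is fixed for them; traits are summarised over one
value per population (they are homogenised within populations).

## Statistics

Level-vs-level regressions log-transform all diversity measures except
species MPD (whose distribution needs no transform), dropping
non-positive values; simulations are equally weighted. Multiple
regressions standardise the six parameters (so coefficients are
comparable effect sizes) and reduce terms by bidirectional greedy AIC
stepwise selection from the full model; with ≤ 6 predictors the greedy
search is validated against exhaustive subset enumeration in the tests.
Spearman correlations between continuity metrics and clade properties
report Bonferroni-multiplied p-values uncapped (matching the convention
of published tables where p can exceed 1) alongside a capped column.
The PCA standardises the clade properties; loadings and percent
variance are reported. The whole analysis is a pure function of the
metrics table.

## Reproducibility and numerical conventions

- One seeded generator per simulation, consumed in a documented fixed
  order (dispersal then traits, species in ascending id); identical
  landscape + parameters + seed give bit-identical runs. Ensemble run
  *i* uses seed `master_seed + i`, so results are order-independent.
- Ties: parent identity at speciation (largest component, then lowest
  cluster index), colonisation source (lowest cell index), cluster
  renumbering (first occurrence along sorted cell ids) are all
  deterministic.
- Degenerate inputs: a world with no habitable cell at t = 0 raises an
  unseedable-world error; single-tip trees report MPD as missing;
  empty regional subsets report missing values rather than zeros;
  constant columns in correlations are reported missing.
- Floating point: divergence matrices are symmetrised after weighted
  remapping; equality tests in the suite use numpy tolerances.

## Limitations

- Population counts per species are bounded by the handful of banks in
  the study world; the long right tail of population richness seen at
  global scale cannot appear at this extent.
- The competition normalisation constant and the trait
  evenness/diversity indices are package conventions; each is isolated
  in a single function so alternatives can be substituted.
- The divergence decrement does not distinguish one-way from mutual
  gene flow, and colonists inherit source-cell rather than cluster-mean
  traits; both choices are flagged in the code and trivially
  changeable.
- α-diversity (per-cell) continuity is out of scope; only γ (whole
  domain) and β (between bioregions) comparisons are implemented.
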