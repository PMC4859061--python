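# Methods

## Model

A clade diversifies on a time-ordered stack of boolean habitat grids
(tropical shallow-reef cells on a global equal-angle grid, 1-Myr steps, ages
decreasing). State per species is its set of occupied cells plus genealogy
links; the root species occupies all habitat of the oldest slice (or a
configured sub-region, for younger-clade experiments). Each step applies the
speciation phase and then the dispersal phase, in that order.

**Parapatric speciation.** Range cells are partitioned by single-linkage
clustering at the sea-distance threshold *d*ₛ: two cells belong to the same
block iff they are connected by a chain of pairwise distances ≤ *d*ₛ
(density-reachability with a minimum neighbourhood of one point). A range in
*n* ≥ 2 blocks becomes *n* daughter species; the parent is closed at the
split age as a pseudo-extinct internal node (a config flag instead lets the
largest fragment keep the parent identity). Because clustering runs at the
top of a step on the ranges produced by the previous step's dispersal,
a range must remain fragmented across a full 1-Myr step to speciate —
fragments reconnected within the same step never count as separated.

**Sympatric speciation.** Every occupied cell of every species draws an
independent Bernoulli(*P*ₛ) event per step; each event spawns a daughter
whose initial range is that single cell. The parent keeps the cell (true
sympatry; removing it would erode ranges artefactually). Expected events per
species-step are *P*ₛ·*A* for range area *A*. In the combined model the
sympatric draw runs over the assemblage present after the parapatric
sub-phase, daughters of same-step splits included; the ordering
(parapatric first) is fixed, and this choice matters little because same-step
interactions are second-order in *P*ₛ.

**Dispersal and extinction.** Each extant species draws a reach
*r* = min(*x*, *d*) with *x* ~ Weibull(shape κ, scale ρ·*d*); defaults
κ = 2, ρ = ½ put the mean reach well inside the cap while leaving a tail
that occasionally attains it. The kernel shape and scale ratio are exposed
in `SimConfig` because only the kernel family and the cap *d* are fixed by
the model definition; results quoted here use the defaults. The new range is
(old range ∩ next habitat) ∪ {next-habitat cells within *r* of any old-range
cell} — one expansion hop per step, no chaining within a step (chaining
across steps emerges by itself). A species is marked extinct, at the age of
the slice it failed to reach, only when that union is empty. Forced mass
extinctions remove round(fraction·richness) extant species uniformly without
replacement when the simulation arrives at the event's slice.

**Distances.** Default mode is the great-circle central angle between cell
centroids in degrees of arc, matching a formulation that clusters
coordinates directly; a sea-graph mode (shortest path over non-land cells,
8-neighbour moves weighted by centroid angle) is available where a land mask
makes straight lines unrealistic. Both *d*ₛ and *r* comparisons are closed
(ties at the threshold connect), longitudes wrap the short way around, and
the simulator uses the union of land masks across slices when building the
sea graph. For speed the engine caches pairwise distances over the union of
all ever-habitat cells when that universe is ≤ 4000 cells, plus boolean
adjacency at the run's *d*ₛ; above that it falls back to per-query KD-tree
searches on unit vectors (chord radius = 2·sin(θ/2)). Both paths are tested
for exact agreement with a brute-force union-find oracle.

**Randomness.** A root seed spawns one `numpy` Generator per species, keyed
by `[seed, species_id]`. Each species consumes only its own stream (sympatric
cell draws, then the dispersal reach, in fixed order), so creating or
removing one species never perturbs another's draws; this makes the
monotone-dispersal property (same seed, larger *d* ⇒ ranges nest) hold
exactly and testable. Forced-extinction victims use a separate stream keyed
by the step index. Everything downstream (swap nulls, Mantel permutations,
sweep replicates) takes explicit Generators or derives per-run seeds by
hashing (base seed, mode, *d*, *d*ₛ, *P*ₛ, replicate) with BLAKE2, so sweeps
are resumable and order-independent.

**Bookkeeping.** Richness satisfies
extant(t+1) = extant(t) + daughters − (pseudo-extinctions + habitat deaths +
forced deaths) exactly at every step. Diversification rates divide events by
the richness at the step start; a parapatric split counts as one speciation
event per splitting parent (configurable to *n*−1) and pseudo-extinctions are
never extinction events, otherwise every split would cancel itself.
Genealogies serialise to Newick with branch lengths in Myr; parapatric splits
are (possibly multifurcating) internal nodes at the split age, sympatric
births bifurcations along the parent branch, and internal labels carry the
owning species id.

## Summary statistics and model selection

Jaccard dissimilarity 1 − a/(a+b+c) and its turnover component
β_jtu = 2·min(b,c)/(a+2·min(b,c)) are computed for all site pairs (NaN where
undefined, zero diagonal). The among-sites NODF takes, for every site pair
with fill(i) > fill(j), the paired overlap 100·|shared|/fill(j), zero for
equal fills, averaged over all pairs; zero-fill rows are dropped with a
warning. It agrees with R vegan's `nestednodf(..., order=TRUE)` rows
component, which serves as an independent cross-check in the tests. The
sequential-swap null flips random 2×2 checkerboards (preserving all margins
exactly) with a burn-in of 10× the matrix fill before the first sample and
between samples (configurable; the algorithm's chain settings are not
canonical); p = (1 + #{null ≥ observed})/(n_null + 1), one-tailed for
nestedness. Mantel tests correlate lower triangles and permute one matrix's
site labels, one-tailed positive (the distance-decay direction), +1
convention. Packed site orders sort by decreasing fill, ties by decreasing
overlap with strictly richer sites, then label; congruence is Spearman's
rank correlation of two such orders.

Map comparison min–max rescales both maps to [0, 1] (making the fit
invariant to affine rescaling of raw inputs; a flag accepts pre-scaled
inputs), computes RSS (floored at 1e−12 so BIC stays finite), R² from OLS of
observed on predicted, and BIC = n·ln(RSS/n) + k·ln(n) with k = 2, 2, 3 for
the parapatric, sympatric and combined models. Sweeps fit the
replicate-averaged predicted richness map per comparison epoch (per-replicate
fitting available), on the intersection of cells with data — predicted maps
are laid over all habitat cells of the slice so unoccupied habitat counts as
zero, not missing. Simulations are ranked by BIC summed across comparisons;
ties break toward fewer parameters, then label.

## Synthetic landscapes

The generator renders rectangular shelf provinces whose drift is quantised to
whole cells per slice, so province cell counts are constant except at
scripted events — drifting patches, fragmentation episodes (the rectangle is
carved along longitude into fragments separated by a scripted gap, then
reconnects), emergence ages, a west-edge encroachment rate (closing seaways)
and a two-province collision whose facing gap shrinks to adjacency exactly at
the merge age. It emulates the features of reconstructed paleobathymetry that
drive the model — patch disconnection/reconnection and province collision —
but not bathymetric detail, curved shorelines, volcanic islands or
latitudinal habitat asymmetry; passing tests therefore validate the engine's
mechanics and statistical behaviour, not the realism of any particular
reconstruction. Real habitat stacks enter through the NetCDF (time/lat/lon,
0/1 bytes, centre registration) or per-age ESRI ASCII readers, and fossil
occurrence tables drive the tropical-limit estimator (95th percentile of
absolute paleo-latitude over occurrences whose closed age interval overlaps
the slice, applied as ±limit — one symmetric percentile is robust to
hemisphere-biased sampling) and windowed fossil diversity maps (distinct
species per 40°×40° window centred on each cell centroid, longitude-periodic,
truncated at the poles, min–max rescaled; an all-zero map returns zeros with
a warning rather than erroring).

## Benchmark problem sizes

The test suite and the acceptance script run everything on synthetic
landscapes whose habitat occupies a window of a global 1° grid (a few hundred
ever-habitat cells, 140 slices), with 5 replicates per parameter combination
in sweeps — large enough for every qualitative regime of the model (hotspot
movement, faunal fusion, the degenerate d > d_s explosion) while a full 7×7
parameter-recovery sweep over 10 base seeds completes in minutes. The
parameter-recovery benchmark deserves a note: because map fits rescale away
absolute richness, the split threshold *d*ₛ is identifiable only through
spatial structure, so the benchmark landscape fragments the western part of a
30-cell shelf with gap widths sweeping the *d*ₛ range (split history
accumulates as a persistent west–east richness gradient) and places offshore
islands at graded distances to pin down *d*. Sweeps there use a species cap
of 250 as the abort threshold for the degenerate d > d_s regime — on a
~380-cell landscape that count already means "all species everywhere"; the
cap is purely an abort guard, and capped runs are recorded as failed and
excluded from ranking.

## Known limitations

No niche evolution, temperature or acidity forcing, Quaternary sea-level
cycles, hybridisation or introgression: speciation and extinction respond to
habitat geometry alone. The Weibull kernel's shape and scale ratio are
package defaults, not canonical values. The sequential-swap chain samples the
fixed-margin matrix class without a formal uniformity guarantee (the
classical caveat for this null model). Sea-graph distances use a single
static land mask per run rather than per-slice masks.
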