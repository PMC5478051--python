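# Methods notes

This note records the modelling assumptions, default parameters and
numerical conventions behind `riverscape`, and what the synthetic test
system does and does not establish about real data.

## Coordinate and distance conventions

All coordinates are WGS84 longitude/latitude in decimal degrees; all
distances are meters on a sphere of radius 6,371,000 m (the conventional
mean Earth radius, fixed as a constant for bit-reproducibility). Great-
circle distances use the haversine formula; one degree of arc is therefore
111,194.93 m everywhere. Missing distance-matrix entries are NaN in memory
and `NA` in CSV output.

## Snapping and river-network distance

Sample points are moved to the nearest point of the river network before
any geographic distance is computed. Nearness is evaluated per point in a
local equirectangular frame centered on that point (x scaled by cos φ), so
the projection onto each polyline arc is planar while frame distortion over
realistic snap distances (≤ tens of km) stays far below the network's own
positional uncertainty. The offset moved is recorded per sample.

The river graph has a node at every arc endpoint — junctions are matched by
rounding coordinates to 1e-6° (≈ 0.1 m), the usual tolerance for
shapefile-derived networks — plus one node per snapped sample, inserted by
splitting its arc at the snap position. Edge weights are summed haversine
lengths of the polyline pieces. River distance is the shortest path in this
graph; samples in different connected components (isolated basins) get a
missing entry, which the Mantel machinery — not the distance engine — must
handle. Within one basin the river distance can never beat the great
circle; the test suite checks this with a 0.1% tolerance for the
spherical/planar mixing introduced by snapping.

## Least-cost-path distance

The altitude raster becomes an 8-connected cell graph. The conductance of a
cell transition is a pluggable function of the two cell altitudes; the
default is `inverse_mean_altitude`, c = 2/(h₁+h₂) with altitudes floored at
1 m, so higher terrain costs proportionally more to cross. No published
convention fixes this function for any particular species, which is why it
is configuration rather than a constant. Conductances are geo-corrected —
divided by the haversine distance between the two cell centers — so edge
costs are distance/conductance and carry length units: over flat terrain of
altitude 1 the LCP between two cells on a grid row equals their great-circle
separation exactly. Endpoints resolve to the containing cell's center;
sub-cell offsets are ignored, matching standard raster-graph semantics.

Two numerical caveats. First, an 8-connected lattice elongates arbitrary
directions by up to 1/cos(22.5°) ≈ 1.082; that bound is exact only where
cells are square *in meters*, i.e. near the equator — at latitude 42° the
lon/lat anisotropy (dx ≈ 0.74 dy) pushes the worst direction to ≈ 1.10. The
elongation tests therefore run on an equatorial raster. Second, because the
default conductance decreases with altitude, raising any cell can never
shorten any path; this monotonicity is property-tested.

## Mantel test

The statistic is the Pearson correlation over off-diagonal upper-triangle
pairs valid (non-missing) in both matrices. Permutations relabel the second
matrix's rows and columns jointly; missing entries travel with the
permutation and the valid-pair set is recomputed each time, preserving the
"disconnected pairs are missing data" semantics under the null. The
p-value is two-tailed with add-one smoothing,
p = min(1, 2·min(#{r\*≥r}+1, #{r\*≤r}+1)/(B+1)), so the floor at B = 9,999
is .0002 — the convention that reproduces the customary permutation-test
floor reported by riverscape isolation-by-distance studies. An exhaustive
mode enumerates all n! relabelings (identity included, p = 2·min(ge,le)/n!)
and is the oracle the sampled mode is tested against. Comparisons use a
1e-12 tolerance so ties (e.g. a permutation reproducing r exactly) count as
extreme.

## AMOVA

One-way analysis of molecular variance on squared pairwise distances:
SSD_total = (1/N)Σ_{i<j} d²ᵢⱼ, SSD_within = Σ_g (1/n_g)Σ_{i<j∈g} d²ᵢⱼ,
SSD_among by difference; mean squares by df (G−1, N−G); the unequal-size
coefficient n′ = (N − Σn_g²/N)/(G−1); σ²_w = MSD_within,
σ²_a = (MSD_among − MSD_within)/n′, Φ_ST = σ²_a/(σ²_a+σ²_w). σ²_a is *not*
truncated at zero, matching standard implementations and keeping the SSD
decomposition exact; Φ_ST can therefore be slightly negative on
unstructured data. The p-value permutes group labels and counts Φ\* ≥ Φ
with add-one smoothing (default 999 permutations — the permutation count
for this test is a convention, not a derived quantity). The among-group
percentage reported is 100·Φ_ST.

## Windowed diversity and interpolation

Nucleotide diversity π is the mean over unordered sequence pairs of the
per-site difference proportion. Ambiguous characters (N, gaps) are deleted
*pairwise* by default — each pair is compared over its own unambiguous
sites — because noninvasive samples (feces, predated remains) yield N-rich
sequences and complete deletion can discard most of the alignment; complete
deletion is available as an option since published π values do not always
state their convention. The spatial window around each sampling point
includes every sample within the radius (default 10 km), the focal sample
included; windows with fewer than two samples are undefined (missing).
Per-basin summaries report both the mean of per-point window values (the
default) and pooled per-basin π, since either reading is defensible when a
study reports "averages per basin".

IDW interpolation uses power 2 (the default of the gstat family of
implementations) on a lattice of square cells of `grid_cell_m`/111,194.93
degrees — exactly 1 km in latitude at the default; longitude cells are
narrower by cos φ. Projected-CRS support is deliberately out of scope. A
point within 1 m of a cell center contributes its value exactly; IDW values
are convex combinations and can never leave the input value range.

## Genetic distances

Patristic distances (sum of branch lengths on the tip-to-tip path) are
extracted from any Newick tree with branch lengths; maximum-likelihood tree
inference is intentionally delegated to external tools, since the analysis
needs only the distances. When no tree is supplied the pipeline builds a
Saitou–Nei neighbor-joining tree from pairwise p-distances (pairwise
deletion). The NJ implementation is deterministic: Q-criterion ties break
on the smallest (i, j) index pair and negative branch lengths are clamped
to zero, so repeated runs are bit-identical; on additive matrices the
output reproduces the input distances exactly, which is the main test.

## The synthetic riverscape

The generator defines the study conditions for all stochastic tests; no
published generative model exists for this kind of empirical system, so the
choices below are the package's own and are fixed once.

* **Networks**: one planar binary tree per basin, grown northward from an
  outlet on a common baseline; trunk length 0.25°, child arc lengths decay
  by 0.6 per level, branch angles drawn uniformly from ±(0.35–0.9) rad with
  headings clamped to ±1.1 rad of north, basins spaced 0.8° apart. Depth 4
  gives 31 arcs and ≈ 140 km of river per basin — the scale of a small
  Iberian drainage.
* **Altitude**: elevation = 200 m + 0.02 × (along-network distance from the
  basin outlet, m) + a 500 m Gaussian ridge (width 0.12°) midway between
  adjacent basins, sampled on a 0.02° grid covering the network bounding
  box padded by two cells. The 2% channel slope yields realistic ~1,500 m
  headwaters; the ridge creates the overland-versus-river contrast the
  analysis is meant to detect. The basin outlet is identified as the
  southernmost endpoint, consistent with how the generator grows networks.
* **Samples**: placed length-uniformly over the network (position drawn on
  the total length, then located along its arc), so reach density is
  constant; basin labels come from the arc.
* **Genealogy**: target distances G = α·geo·ε with ε lognormal(0, σ²)
  symmetrized by averaging — multiplicative noise keeps distances positive
  and symmetric — then neighbor joining. α defaults to 10⁻⁶
  substitutions/site per meter so that 50 km of river separation produces
  5% sequence divergence, mitochondrial-like over postglacial timescales;
  σ = 0.2 gives ±20% scatter around the isolation-by-distance line.
* **Sequences**: HKY85 (κ = 2, equal base frequencies, 1,066 sites —
  matching a two-fragment mtDNA alignment) simulated site-independently
  with exact per-branch transition matrices expm(Qt), Q scaled to one
  expected substitution per site per unit branch length. No rate
  heterogeneity, recombination or selection.
* **Inter-basin connectivity (generation only)**: river distances between
  disconnected basins are completed by joining outlets —
  d(i→outlet) + great-circle between outlets + d(outlet→j) — i.e. the
  basins touch at the coast. The *analysis* side never sees these values;
  its river matrices keep missing entries exactly as disconnection
  semantics demand.

Because genealogies are built by NJ from noisy distances rather than drawn
from a coalescent, the synthetic data lack incomplete lineage sorting,
demographic history and rate variation; passing the recovery test shows the
*pipeline* can distinguish river- from land-driven isolation by distance at
this scale and noise level, not that any particular real dataset can.

## Scales and seeds

Stochastic test sizes were chosen to make the checks sharp at desk scale:
sequence-level oracles use 100,000 sites (Monte-Carlo SEs ≈ 0.001),
permutation-uniformity checks use 500 replicates of 199 permutations, and
the recovery experiment runs 20 independent replicates per generating model
at the default configuration (2 basins, 40 samples), requiring ≥ 18/20
wins for the generating distance over its competitor. One global seed is
split hierarchically (numpy `SeedSequence`) into per-stage seeds so stages
stay decoupled; every randomized function takes an explicit seed and all
pipelines are byte-reproducible given one.

## Known limitations

* Lon/lat-only; no projected CRS, so raster cells are metrically
  anisotropic away from the equator (documented above where it matters).
* The LCP conductance function and raster resolution are conventions, not
  estimates; conclusions can be sensitive to both.
* One-way AMOVA only (no hierarchical designs), full Mantel only (no
  partial Mantel), and no kriging alternative to IDW — all deliberate
  scope boundaries.
* Dams and other anthropogenic barriers are not modelled in the river
  graph.
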