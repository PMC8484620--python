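# Methods

## Scope and data model

`fragtrack` operates on pixel-aligned binary forest/non-forest rasters
in a projected, equal-area CRS. The package deliberately does not
derive forest maps (classification of imagery, digitisation) and does
not reproject: inputs are assumed already binary, already aligned, and
misalignment is an error rather than an implicit resample. Areas are
`pixel count × pixel_size²`; no geodesic correction is applied.

Nodata cells are excluded from landscape area and treated as
non-forest wherever a binary decision is needed (distance transforms,
perimeters, change maps). This is explicit rather than configurable
magic: a nodata cell can never be forest, so any statistic over forest
is unaffected; only the denominator conventions (landscape area for
edge density) change, and those use the valid-cell count.

Raster I/O uses ESRI ASCII grids with a JSON sidecar. The format is
plain text, diff-able, and read natively by GDAL/ArcGIS/QGIS; the
sidecar carries what the header cannot (CRS id, epoch year, class
codes, classifier parameters) so a class raster is self-describing.

## Fragmentation model

Let *F* be the forest mask and *d(p)* the exact Euclidean
centre-to-centre distance from pixel *p* to the nearest non-forest
pixel (scipy's exact EDT). The classifier, with edge width *w*
(default 100 m):

1. **Core candidates**: forest pixels with *d(p) > w* strictly. With
   30 m pixels and *w* = 100 m this means at least 4 pixels
   orthogonally (√11·30 ≈ 99.5 m is not core; √12·30 ≈ 103.9 m is).
   Distances are square roots of integer sums of squares scaled by the
   pixel size, so threshold comparisons are reproducible bit-exactly.
2. **Core size classes**: contiguous core tracts (8-connected) are
   core1 below 250 acres, core2 in the closed interval [250, 500]
   acres, core3 above. The defaults use the exact international-acre
   conversion (1.0117141056 and 2.0234282112 km²); both thresholds are
   parameters, so rounded conventions can be substituted.
3. **Holes**: non-forest components at 4-connectivity that do not touch
   the grid boundary. Forest at 8- and holes at 4-connectivity is the
   standard duality that prevents a diagonal pixel line from both
   connecting forest and sealing a hole. `max_hole_area` (default
   unlimited) lets very large interior openings count as exterior.
4. **Perforated vs edge**: a non-core forest pixel is perforated iff
   its nearest non-forest pixel lies in a hole *strictly* nearer than
   any exterior non-forest; exact ties resolve to edge. This is
   implemented as two distance transforms (to hole cells, to exterior
   cells) compared per pixel, which makes the tie rule explicit and
   testable. Published tool manuals do not pin down a tie rule; one had
   to be fixed, and strict-to-hole is the conservative choice (edge is
   the more exposed class).
5. **Patch override**: 8-connected forest fragments containing no core
   pixel are relabelled patch wholesale, overriding step 4. No size cap
   is applied beyond the no-core criterion.

Boundary policy: under `outside_is_nonforest` (default) a virtual ring
of non-forest borders the grid, so map-edge forest can never be core
when *w* ≥ one pixel; under `outside_is_forest` the world beyond the
raster is forested and an all-forest grid is entirely core. Which
policy a given published map used is usually unstated, so both are
supported and recorded in the class raster's sidecar.

Every forest pixel receives exactly one class, so per-class areas sum
to total forest area exactly in pixel counts — this conservation
identity is asserted throughout the test suite and holds for every
input, not just fixtures.

## Landscape metrics

Patches are 8-connected forest components. The raster perimeter is the
count of pixel edges adjacent to non-forest times the pixel size;
grid-boundary edges count only under `outside_is_nonforest`. Metrics:
NumP; MPS and PSSD in km² (PSSD uses the population ÷N estimator —
the patch set is the whole population, not a sample); total edge E =
Σpᵢ; ED = E / landscape area (m/km², denominator the full valid
landscape, the FRAGSTATS convention); MPE = E/NumP; MSI =
mean(0.25·pᵢ/√aᵢ); MPAR = mean(pᵢ/aᵢ) reported in m/ha; MPFD =
mean(2·ln(0.25·pᵢ)/ln aᵢ).

MSI and MPFD default to the raster-adjusted normalisation because the
vector forms misbehave on pixel data: a single square of pixels — the
minimal raster shape — scores exactly 1.0 under the adjusted forms but
2/√π ≈ 1.13 under `p/(2√(πa))`. The vector forms remain available via
`vector_formulas=True` since published tables rarely state which
variant produced them. An empty landscape yields NumP 0 and NaN for
every ratio metric rather than an exception.

Because absolute metric values are sensitive to map extent, resolution
and the (undeposited) source maps of any given study, the package's
tests pin the metrics to closed forms and oracles on constructed
fixtures and to *qualitative direction* on simulated loss series
(NumP↑, MPS↓, ED↑, MPAR↑), not to any published absolute metric table.

## Change analysis

Percent change is 100·(a₂−a₁)/a₁; the annual rate is the
continuous-compounding 100·ln(a₂/a₁)/(t₂−t₁). Both are signed
internally (loss negative); report writers print magnitude plus
direction because published tables mix sign conventions. a₁ = 0 yields
a missing value; a₂ = 0 yields a −∞ rate with a warning. Rounding to
2 dp happens only at the reporting layer (round-half-even via C
`%.2f`).

Grid summaries assign each pixel to exactly one cell by pixel-centre
membership in half-open cells anchored at the raster origin (the
anchor is a convention; published grid analyses rarely state theirs).
Cell categories over the first/last epoch pair: `complete_loss`
(a₁ > 0, a₂ = 0), else `deforested` (Δ < 0), `gain` (Δ > 0), `stable`.
Cross-tabulations count pixel pairs of fragmentation classes between
two epochs classified with identical parameters; marginals equal the
per-epoch class summaries exactly, and the matrix total is the
landscape area.

Regional reports classify fragmentation once on the full landscape and
then tabulate within region masks (pixel-centre point-in-polygon via
shapely), so region boundaries never create artificial forest edges.

## Synthetic data generator

The generator emulates the regime the analysis machinery is built for:
a largely intact, spatially clumped forest landscape losing cover over
nine decades at a small compound rate.

* **Neutral landscape**: white noise filtered in the Fourier domain
  with amplitude ∝ f^(−β/2) (power spectrum f^−β), thresholded at the
  empirical quantile so the achieved forest fraction is exact to one
  pixel with deterministic tie-breaking. Spectral synthesis was chosen
  over cluster-growth models because it is parameter-light, seedable
  and fraction-exact. Defaults: 30 m pixels, cover fraction 0.57 (the
  1930 forest share of the reference landscape), β = 3 (strongly
  clumped, contiguous tracts).
* **Deforestation**: each simulated year removes exactly
  `round(A·(1 − e^{r/100}))` cells from the current count *A* —
  deterministic expected-value rounding, with randomness only in
  *which* cells go. This separates estimator correctness from
  Monte-Carlo noise: the compound-rate estimator applied to the first
  and last snapshots recovers the configured rate to well within
  ±0.02 %-points on a 500×500 grid. Removal probability is
  ∝ exp(edge_bias/(1+d)) on the current-year distance map (grid
  boundary counting as non-forest); edge_bias 0 is spatially random
  clearing, the default, since no spatial clearing model is assumed.
  Weighted sampling without replacement uses the Gumbel top-k trick
  (exact Efraimidis–Spirakis sampling, vectorised). If the forest is
  exhausted before the final epoch the simulation warns and continues
  at zero. Positive rates are rejected: this is a loss simulator.
* **Conflict points**: each point independently falls uniformly inside
  a loss pixel with probability `p_in_loss` (default 0.60) else
  uniformly inside a non-loss pixel. With n = 5000 the recovered
  fraction is within the binomial 3σ band (±0.021) of the target.

What the generator does *not* emulate: real geography, terrain, roads
or settlement patterns; correlated multi-year clearing fronts; map
digitisation error in historical epochs; registration error between
epochs. Passing tests on synthetic series therefore demonstrate the
correctness of the *measurement machinery* (classification, metrics,
rates, overlays), not the realism of any particular landscape history.

## Problem sizes and determinism

Test fixtures are ≤ 50×50 where a brute-force oracle (exhaustive
nearest-pixel scan, flood fill, per-edge perimeter count) is compared
pixel-for-pixel; simulations use 100×100–500×500 grids, sized so the
full suite runs in seconds. All randomness flows through
`numpy.random.default_rng` seeded from explicit config fields; the
pipeline re-seeds its simulation from the config seed and writes
SHA-256 checksums, making reruns byte-identical.

## Known limitations

* Single-class (forest) analysis only; no multi-class land-cover
  transitions beyond the six fragmentation classes.
* No CRS reprojection or geodesic areas; inputs must share a grid.
* Perimeter is the raster (rook) perimeter; no polygonal smoothing, so
  shape metrics carry the usual raster bias at coarse resolutions.
* The conflict overlay reports a raw overlap fraction; it is not a
  statistical attribution of conflict to forest conversion.
* Gain simulation is out of scope for the generator (analysis of gain
  in real rasters is supported).
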