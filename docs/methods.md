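# Methods

This note documents the models implemented in `karsthealth`, the choices
made where the methodology was genuinely open, and what the synthetic study
systems do and do not establish about real data.

## Landscape metrics

Patches are connected components of same-class cells, 8-neighbour (queen)
connectivity by default — the Fragstats convention — with 4-neighbour
available everywhere. Perimeter is the count of cell sides facing a
different class, a nodata cell, or the raster boundary, in cell-edge units;
multiplying by the cell size gives metric perimeters when the raster is
georeferenced. nodata cells are excluded from cell totals, class proportions
and adjacency counts, but edges against nodata do contribute perimeter
(a hole in the landscape has a boundary).

* SHDI = −Σ pᵢ ln pᵢ (nats; 0·ln 0 ≡ 0); SHEI = SHDI/ln m over the m classes
  present, defined as 0 for single-class landscapes.
* COHESION = 100·[1 − Σpᵢⱼ / Σ(pᵢⱼ√aᵢⱼ)] / [1 − 1/√N], landscape-wide over
  all patches, N the number of valid cells. Undefined (error) at N = 1.
* CONTAG = 100·[1 + ΣᵢΣₖ qᵢₖ ln qᵢₖ / (2 ln m)], qᵢₖ = Pᵢ·gᵢₖ/Σₖgᵢₖ, with the
  adjacency counts gᵢₖ under the double-count convention (each internal cell
  side counted once per direction). Errors for single-class landscapes.
* FRAC_MN averages 2 ln(0.25 pᵢⱼ)/ln aᵢⱼ over patches; single-cell patches
  (ln a = 0) take the value 1, consistent with squares having dimension 1.

A noteworthy property verified exhaustively in the tests: the 2-class
checkerboard does **not** minimize CONTAG. It concentrates all adjacencies
on the unlike pair, whereas mixed mosaics spread the adjacency distribution
over all class pairs and reach lower contagion. Intuition that equates
"checkerboard" with "minimal contagion" holds for like-adjacency fractions,
not for the entropy-form index.

## Indicators

ESV uses the equivalent-coefficient method: Σ (class area × per-class value
coefficient). Published benchmark coefficient tables are deliberately not
bundled; the table is a configuration input, and the default used in tests
and synthetic runs is synthetic (labelled as such in
`pipeline.SYNTHETIC_ESV_COEFFICIENTS`). LUI is the area-weighted mean of
ordinal intensity grades (construction 4, arable 3, grassland 2.5, forest 2,
water 2, unused 1), bounded in [1, 4] and invariant to resolution
refinement. NDVI band math ((NIR−R)/(NIR+R)) is provided as a utility;
satellite preprocessing is out of scope — NDVI normally enters as a
precomputed raster or zone column. Zonal means assign a cell to a zone when
its centre falls in the polygon, and flag zones covering no valid cell with
NaN rather than a silent zero.

## Entropy-weighted EHI

Normalization is pooled min–max over all zone-year observations per
indicator — not per-year — so scores are comparable across epochs and
trends in EHI are meaningful; per-year pooling can be had by scoring years
separately. Negative indicators use the orientation-reversing form
(max−x)/(max−min), which keeps every normalized value in [0, 1] as the
entropy step's logarithms require. Entropy weights then follow
Eᵢ = −(1/ln n)Σfᵢⱼln fᵢⱼ with n the pooled observation count,
dᵢ = 1 − Eᵢ and wᵢ = dᵢ/Σdᵢ (the only normalization consistent with
Σwᵢ = 1). A constant indicator normalizes to zero, carries no information
and receives weight 0, with a warning. Criterion-layer (pressure/state/
response) weights are reported as sums of member indicator weights. Weights
are always recomputed from the data at hand, never hard-coded.

Grade boundaries are half-open and lower-inclusive from grade II upward
(I [0, 0.5), II [0.5, 0.55), III [0.55, 0.6), IV [0.6, 1]), so every value
in [0, 1] receives exactly one of four grades. EHI-change levels partition
[0.06, 0.13] the same way (closed at 0.13); values outside that band are
labelled out-of-range rather than forced into a level.

The `EntropyWeightScorer` estimator follows the scikit-learn transformer
contract (`fit` learns extrema and weights, `transform` maps raw indicator
rows to composite scores, clipping out-of-range inputs into [0, 1]).

## Spatial autocorrelation

Contiguity is queen (any shared boundary point) by default, rook by option,
row-standardized; islands are retained with zero rows and a warning. Global
Moran's I uses the standard cross-product form with the Cliff–Ord
randomization variance for the z-score, plus a one-sided permutation pseudo
p-value ((extreme+1)/(n_perm+1), seeded). Local Moran uses
Iᵢ = (zᵢ/m₂)ΣⱼWᵢⱼzⱼ with m₂ = Σz²/n, so Σᵢ Iᵢ = S₀·I exactly (verified to
1e-10); inference is by conditional permutation holding the focal value
fixed, and cluster labels (H-H, L-L, H-L, L-H) are assigned from the Moran
scatterplot quadrant only where the pseudo p falls below α = 0.05
(configurable). Permutation p-values are invariant under affine transforms
of the data, as they must be.

A caveat the tests make explicit: conditional permutation cannot flag a
spike in an otherwise homogeneous background — if all other values are
equal, every permutation reproduces the observed lag. Significance requires
background heterogeneity.

## GTWR

The kernel is Gaussian in the combined squared space–time distance
d² = Δu² + Δv² + τΔt² (bisquare available); τ ≥ 0 converts time units into
map-distance units and τ = 0 collapses the model to GWR; h → ∞ collapses it
to global OLS (both verified to 1e-6 relative as oracle equivalences). At
each observation a weighted least-squares system is solved by Cholesky
factorization; rank deficiency raises an error naming the observation and
suggesting a larger bandwidth. The hat diagonal Sᵢᵢ = Aᵢ(AᵀWA)⁻¹Aᵢwᵢ feeds
the corrected Akaike criterion AICc = n ln σ̂² + n ln 2π + n(n+tr S)/(n−2−tr S),
minimized by golden-section search over h (bounded by 0.02–4× the spatial
domain diameter), nested in a coarse τ grid when τ is not fixed; the search
is deterministic. Coordinates must be planar before fitting (project first;
the synthetic systems are already planar), and time is numeric (e.g. years
since the first epoch).

VIF screening regresses each candidate driver on the others and removes the
highest-VIF driver iteratively while any exceeds the threshold (default
7.5); perfectly collinear drivers have infinite VIF and go first. The
screen is exposed both as a function returning a per-round report and as a
scikit-learn transformer.

Coefficient surfaces are summarized by per-driver, per-year quantile
binning into four ordered levels (fewer when ties collapse bins, with a
warning), with the positive/negative driving split reported separately.

## Synthetic study systems

The generator emulates a multi-county panel over five epochs (default
2000–2020 in 5-year steps, 88 zones on an 8×11 lattice, 100×100 cells per
zone — desk-scale stand-ins; the zone count and panel dimensions of any
particular real study are inputs, not constants of the method).

* **Zone maps** are rectangular lattices, chosen over irregular polygons so
  the queen/rook contiguity structure is analytically known and the spatial
  statistics can be tested against it. Prime zone counts are rejected
  (no r×c layout with r, c ≥ 2 exists).
* **Land-use panels** threshold a smoothed Gaussian random field (kernel
  width = `autocorr_range`, default 8 cells — mosaic-scale patchiness) at
  the standard-normal quantiles of the target class proportions
  (construction/arable/grassland/forest/water/unused defaulting to
  5/30/20/35/5/5%, a forest-and-arable-dominated karst-like mosaic). The
  field is standardized per raster, so realized proportions fluctuate
  around the targets and shrink toward them as the grid grows (verified at
  two grid sizes) instead of being pinned exactly — giving zones and epochs
  genuinely different compositions. Epoch t+1 blends epoch t's latent field
  with a fresh one at weight (1 − persistence), so persistence = 1 freezes
  the landscape.
* **Driver panels** draw drivers from smooth spatial fields plus zone-level
  Gaussian scatter (`driver_noise_sd`) and generate the response from true
  coefficient surfaces β(u, v, t) plus N(0, noise_sd²) noise. The true
  coefficient arrays are returned in a separate sealed record, row-aligned
  with the panel, so recovery tests can score estimates without the
  observable panel leaking the answer.

The reference recovery scenario (`recovery_scenario`) uses 88 zones ×
5 epochs = 440 observations, all coefficient surfaces bounded away from
zero, response noise sd 0.05 and driver scatter sd 0.5 — the scatter is
deliberately generous because local slope identifiability requires driver
variation *within* a kernel neighbourhood; with drivers that are smooth
functions of space alone, the local design matrix degenerates and no local
method can separate coefficient surfaces from driver surfaces. In the
strong-variation variant the precipitation coefficient sweeps ≈0.2→2.2
across the west–east axis, a signal a global regression cannot represent.

**What passing tests do and do not show.** The synthetic systems exercise
the full computational chain with known answers, but they idealize real
data: zones are equal-area rectangles (real counties vary in size and
shape, which affects contiguity and metric scales), class proportions are
stationary targets (real land-use change is directional), drivers have
spatially uncorrelated noise (real covariates share terrain-driven
structure), and the response is exactly linear in the drivers. Passing
recovery tests therefore demonstrates correctness of the machinery, not
that any real landscape satisfies the model.

## Numerical and interface choices

* Raster I/O: integer TIFF via tifffile, and the plain-text ESRI ASCII grid
  format for portable interchange; zone polygons as GeoJSON via shapely.
  Georeferencing is an axis-aligned affine (origin + square cell size).
* Patch delineation delegates connected-component labelling to
  scikit-image; the test suite cross-checks it against an independent
  cell-by-cell flood fill, and VIF against statsmodels'
  `variance_inflation_factor`.
* Entropy weights guard 0·ln 0 ≡ 0, clip vanishing negative difference
  coefficients from rounding, and error when every indicator is constant.
* All permutation inference takes an explicit seed; the pipeline derives
  stage seeds deterministically from the scenario seed, so a rerun with the
  same config writes byte-identical CSVs (the run manifest's wall-clock
  timings excepted).
* Pipeline problem sizes in the test suite (9–25 zones, 15×40-cell rasters,
  49–999 permutations) are desk-scale choices that keep the full suite
  under ten seconds; all algorithms are O(n²) or better in the zone count
  except LISA's conditional permutations, which dominate large runs.

## Known limitations

* No area-weighted provincial EHI aggregation by default (simple zone means
  are reported; area weighting is an option flag on grade shares).
* CONTAG and COHESION follow Fragstats' raster conventions; no vector-based
  landscape metrics, moving-window analysis or additional Fragstats indices.
* GTWR offers no mixed global/local terms and no bootstrap confidence bands
  for local coefficients; inference on coefficient surfaces is descriptive
  (quantile levels and sign shares).
* The ESV equivalent-coefficient framework takes coefficients as given;
  localizing benchmark prices to a study region is the user's
  responsibility.
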