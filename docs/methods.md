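# Methods

## Model and assumptions

dasypop performs dasymetric downscaling of country-level population
scenarios under a land-use constraint. The state at year *t* is a fine
lattice of people per pixel; the only drivers are (a) per-country totals
and urban shares for year *t* and (b) a coarse urban-fraction grid for
year *t*. The method assumes:

- population redistributes only through the urban/rural strata — there is
  no migration model, no suitability surface beyond the two perturbation
  layers, and no sub-national input;
- the urban fraction refers to the *area* share of a coarse cell, so the
  urban pixel target is computed from the full R² pixel count and then
  capped at the cell's land-pixel count (water is never urbanized);
- within a (country, stratum) set, relative pixel weights persist from
  one year to the next (proportional allotment), so the spatial pattern
  changes only where the mask reclassifies pixels;
- coordinates are geographic (lon/lat, WGS84); all distances are planar
  Euclidean in degree space. Near the equator this is a good
  approximation; toward high latitudes east–west distances are
  overestimated relative to ground distance. This mirrors simple raster
  distance tooling and is accepted as a known distortion — the distances
  only feed a rank-order perturbation, so only their ordering matters,
  and that ordering is distorted only anisotropically.

## Grids and orientation

Both lattices are north-up and row-major: row 0 is the northernmost,
`origin_lon/lat` is the top-left corner of pixel (0, 0), and spans are
half-open and 0-based. Fine shape must be divisible by the refinement R
so coarse cells tile the fine lattice exactly; inputs that do not align
with the run geometry are nearest-neighbor resampled at load time (each
target pixel takes the source pixel containing its center). A coarse
cell is treated as meaningful if it contains at least one valid fine
pixel.

## Tie-free ranking

The ranking surface is `population + rescaled_inv_dist_roads +
rescaled_inv_dist_COG`. Numerical choices:

- **Inverse distance at d = 0.** 1/d diverges on roads, so the inversion
  is v = 1/(d + δ) with δ = one fine cell size. δ must be positive; tying
  it to the cell size keeps the transform scale-appropriate under grid
  refinement while preserving strict order reversal.
- **Rescale bounds** default to 1.0·10⁻⁵–1.1·10⁻⁵ people. The bounds are
  deliberately far below one person so that pixels differing by even a
  hundredth of a person can never swap rank; the sum of both layers is at
  most 2.2·10⁻⁵, which is the perturbation bound asserted in tests.
- **Rescale scope is global** (one affine map over the whole valid
  domain per layer), not per coarse cell or per country: the layers are
  continent-wide surfaces added once to the baseline. The layer's valid
  mask defines the domain over which the extremes are found, so over
  land the rescaled layer attains exactly the bounds.
- **Tie-break.** Exact value collisions are resolved by row-major pixel
  index (stable argsort of the negated values). This gives a strict
  total order, bit-identical masks across runs, and a testable
  separation property (weakest urban ≥ strongest non-urban per cell).
- **Rounding** of the urban pixel target is half *away from zero*, fixed
  explicitly because banker's rounding would silently change urban
  counts for half-integer targets.
- The perturbation layers are added **once, at baseline**. Later years
  rank the previous year's output directly; the index tie-break alone
  guarantees uniqueness there. Re-adding perturbations annually would
  accumulate spurious mass and is avoided.

## Allotment edge cases

- A stratum with pixels but zero previous-year weight and a positive
  target receives uniform shares (deterministic, conserves mass).
- A stratum with *no pixels* and a positive target hands the target to
  the country's other stratum — e.g. a country whose cells have zero
  urban fraction but a nonzero scenario urban share. The alternative
  (dropping the mass) would violate conservation silently.
- A country present on the raster but missing from the series is a hard
  error; the reverse is a logged warning. Losing population silently is
  never acceptable; a series row without territory is merely unused.
- Pixels may switch stratum between years (fractions need not be
  monotone); a pixel's weight is its previous-year population regardless
  of its prior stratum.
- The first projected year is itself a scenario-consistent
  redistribution (using the unique population as weights), so *every*
  published year satisfies conservation — the baseline grid is an input,
  not an output.
- Country scenario series arriving at multi-year steps are linearly
  interpolated to annual resolution; provided steps are reproduced
  exactly and extrapolation outside the provided span is refused.

A fixed-point property follows from the design: with constant totals,
shares and fractions, the loop reproduces the same grid every year
provided the reallotment does not demote urban pixels below rural ones
(urban mean target per pixel ≥ rural mean); the test suite exercises
exactly that regime.

## Scenario selection

The SSP×RCP plausibility matrix is an *input* (its derivation is out of
scope); entries with probability > 0 are selected, in SSP-major order —
15 of the 20 combinations under the default matrix. The probabilities
are used only for inclusion/exclusion, never as weights.

## File conventions

Outputs are single-band float32 GeoTIFFs, nodata −9999, geographic
WGS84, one file per scenario-year named `ssp<ssp>_rcp<rcp>_<year>.tif`
(the naming pattern is this package's documented choice). Geo-tags are
written directly (ModelPixelScale, ModelTiepoint, GeoKeyDirectory,
GDAL_NODATA), so the files are readable by GDAL-based tools. The run
config is YAML with every method constant surfaced as a key, defaults as
above.

## Synthetic worlds

The generator emulates the structure of the real inputs, not their
content: clustered population (isotropic Gaussian bumps over a low
background — enough rank structure for the urban mask to be
interesting), Voronoi countries over a smoothed-random-field land mask,
a trunk road through all country centroids, urban fractions proportional
to baseline cell population drifting linearly upward, and five-year-step
series with compound 2 %/yr growth and linearly rising urban shares.
Per-country baseline totals are distinct by construction (factor
0.6 + 0.4·id) so country-level comparisons have non-degenerate variance.
Default test scale is 2×2 coarse cells at R = 10 (400 fine pixels),
chosen so brute-force subset enumeration in the oracle tests stays
trivial; R = 60 reproduces the reference nesting for demos.

What passing tests on synthetic worlds establish: the algorithmic
contracts — conservation, ratio preservation, top-k optimality,
determinism, format fidelity — under realistic structure. What they do
not establish: demographic realism, behaviour under census-style input
artifacts (zero-inflation, enumeration-area seams), or the quality of
any particular real input dataset.

## Validation statistics

r² is computed about the one-to-one line by default (residuals against
the reference, SS_tot about the reference mean), which is the correct
reading of "everything on the identity line" claims; the regression
variant (squared Pearson correlation) is available via
`compare(..., one_to_one=False)` for comparisons against independent
products where a level offset is expected. Degenerate cases (fewer than
two regions, zero reference variance with nonzero residuals) report r²
as missing with a note rather than a misleading number. RMSE is in
persons. The self-consistency validation (aggregate own output against
own input) is exact up to float64 accumulation, ~10⁻¹⁶ relative.

## Problem sizes

The default test and acceptance configuration uses 2×2 coarse cells,
R = 10, 3 countries, 11 annual steps; a full run at that size takes
tens of milliseconds, and the brute-force oracles (≤ C(9,5) subsets per
cell) stay exact. These sizes are the package's chosen study conditions
for self-validation; all properties checked are scale-free.

## Known limitations

- Planar degree-space distances (see above).
- Nearest-neighbor is the only regridding; area-weighted regridding is
  out of scope.
- No projected coordinate systems.
- External-product comparison (e.g. against an independent gridded
  census product) is supported as a workflow (`compare`,
  `change_report`) but ships with no reference data.
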