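# dasypop

Dasymetric gridded population projections: distribute annual country-level
urban and rural population scenarios (SSP-style) onto a fine
longitude/latitude grid whose urban spatial pattern follows a coarse
urban-fraction raster series (RCP-style land use), year by year.

The package is for modellers who need population as gridded denominator
data — earth-system, food-security, or epidemiological simulations driven
by scenario land-use grids — and for anyone studying how scenario
coupling shapes fine-scale population surfaces.

## Method

Two nested regular lattices share one geometry: fine pixels of size *s*
degrees (30 arc-seconds in the reference configuration) nest *R* × *R*
(default *R* = 60) inside coarse cells (0.5°) carrying an urban fraction
*f* ∈ [0, 1] per year.

1. **Unique population.** Raw population grids are full of ties, so a
   strict per-cell ranking is created by adding two tiny perturbation
   layers to the baseline population *P*: the inverse distance to the
   nearest road and the inverse distance to each coarse cell's
   population center of gravity, each affinely rescaled into
   [1.0·10⁻⁵, 1.1·10⁻⁵] people. Inverse distance is 1/(d + s), bounded
   on roads and strictly order-reversing. Pixels whose populations
   differ by more than the 2.2·10⁻⁵ bound can never swap rank; residual
   exact ties break deterministically by row-major index.
2. **Urban mask.** Per coarse cell and year, the top *k* ranked valid
   pixels are urban, with *k* = round(*f* · *R*²) (half away from zero),
   capped at the cell's land-pixel count.
3. **Allotment.** Each country's scenario total *T* splits into urban
   *U* = *T* · share and rural *T* − *U*; within each (country, stratum)
   pixel set, pixel *i* receives target · *w*ᵢ / Σ*w* with weights *w*
   from the previous year's grid, preserving pairwise pixel ratios and
   conserving every country total exactly.
4. **Annual loop.** Year 0 uses the unique population for both mask and
   weights; every later year ranks the previous year's output against
   that year's urban fractions and re-allots. One run per (SSP, RCP)
   pair; a plausibility matrix selects the 15 combinations with positive
   probability out of the 20 possible.

Validation aggregates any output year back to countries (or admin
regions) and compares against the input series about the one-to-one
line: r² = 1 − SS_res/SS_tot with residuals measured against the
reference, plus RMSE in persons.

A synthetic-world generator fabricates all five inputs (baseline
population, countries/land mask, roads, urban-fraction series, scenario
tables) so the whole pipeline runs and is tested without downloads.

## Worked example

```python
import pandas as pd
import dasypop as dp

spec = dp.SynthSpec(n_countries=3, refinement=10, seed=42, year_end=2010)
world = dp.generate_world(spec)
run = dp.run_world(world, scenario=(1, "4.5"))          # 2000-2010 annual loop

series = dp.annualize(world.series, spec.years)
agg = dp.aggregate_by_region(run.grids[2005], world.countries)
ref = pd.Series({c: series.get(c, 2005)[0] for c in agg.index})
report = dp.compare(agg, ref)
print(report.rows.round(2).to_string(index=False))
print(report.summary())
```

```
 region_id  aggregated  reference  difference
         1   110408.08  110408.08        -0.0
         2   154571.31  154571.31         0.0
         3   198734.54  198734.54        -0.0
regions compared: 3
r-squared (one-to-one): 1.000000
RMSE: 3.85007e-11 persons
```

Each row is one country: the 2005 projection grid summed over the
country's pixels (`aggregated`) against the interpolated scenario total
for that year (`reference`). The differences are float round-off — the
allotment conserves every country total by construction, which is the
method's defining one-to-one validation property.

The same pipeline is scriptable from the shell:

```sh
dasypop synth --seed 3 --out world --years 2000-2005   # fabricate inputs
dasypop project --config world/config.yaml --scenarios ssp1-rcp4.5
dasypop mask --config world/config.yaml --year 2003 --out mask2003.tif
dasypop validate --config world/config.yaml --year 2005 --ssp 1 --rcp 4.5 --out val
```

Outputs are single-band float32 GeoTIFFs (WGS84 lon/lat, nodata −9999),
one file per scenario and year, named `ssp<ssp>_rcp<rcp>_<year>.tif`.

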