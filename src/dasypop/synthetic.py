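"""Synthetic toy worlds for exercising the full projection pipeline.

Real runs need five external inputs: a baseline fine-resolution
population raster, an annual coarse urban-fraction series, country-level
scenario tables, a road network, and country borders doubling as the
land/water mask.  This module fabricates internally consistent stand-ins
for all five on a small nested lattice, so every other module is testable
without any download.

The generated world is deliberately stylised: population is a mixture of
isotropic Gaussian bumps ("cities") over a low uniform background,
countries are nearest-seed (Voronoi) partitions of the land area, water
is the low end of a smoothed random field, roads connect the country
seeds, urban fractions start from the baseline population pattern and
drift upward linearly, and scenario tables follow smooth exponential
growth with linearly rising urban shares at five-year steps.  Everything
is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage

from .allotment import DEFAULT_SCENARIO_MATRIX, ScenarioMatrix, ScenarioSeries
from .core_grids import CoarseGrid, CountryRaster, FineGrid, GridGeometry, pixel_center_arrays

__all__ = ["SynthSpec", "SynthWorld", "generate_world", "worked_example_world"]


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of a synthetic world.

    Defaults give a small world (2x2 coarse cells at refinement 10, i.e.
    400 fine pixels) on which brute-force oracles are feasible; refinement
    60 reproduces the nesting of 30 arc-second pixels in 0.5-degree cells
    at full scale for demos.
    """

    n_coarse_rows: int = 2
    n_coarse_cols: int = 2
    refinement: int = 10
    n_countries: int = 3
    clusters_per_country: int = 2
    baseline_total_per_country: float = 100_000.0
    annual_growth_rate: float = 0.02  # ~2%/yr, a fast-growing-continent figure
    urban_share_start: float = 0.35
    urban_share_annual_increment: float = 0.004
    urban_fraction_mean_start: float = 0.15
    urban_fraction_annual_increment: float = 0.002
    water_fraction: float = 0.1
    year_start: int = 2000
    year_end: int = 2010
    series_step: int = 5
    origin_lon: float = 10.0
    origin_lat: float = 10.0
    fine_cell_size: float = 1.0 / 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_countries < 1:
            raise ValueError("need at least one country")
        if not (0 <= self.water_fraction < 1):
            raise ValueError("water_fraction must lie in [0, 1): an all-water world is infeasible")
        if self.baseline_total_per_country <= 0:
            raise ValueError("baseline totals must be positive")
        if self.year_end < self.year_start:
            raise ValueError("empty year range")

    def country_total(self, country_id: int) -> float:
        """Baseline total of one country: distinct per country so that
        country-level comparisons have non-degenerate variance."""
        return self.baseline_total_per_country * (0.6 + 0.4 * country_id)

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(
            self.origin_lon,
            self.origin_lat,
            self.fine_cell_size,
            self.refinement,
            self.n_coarse_rows * self.refinement,
            self.n_coarse_cols * self.refinement,
        )

    @property
    def years(self) -> range:
        return range(self.year_start, self.year_end + 1)


@dataclass
class SynthWorld:
    """All pipeline inputs for one synthetic world."""

    spec: SynthSpec
    baseline: FineGrid
    countries: CountryRaster
    roads: list
    urban_fractions: dict[int, CoarseGrid]
    series: ScenarioSeries
    matrix: ScenarioMatrix


def _make_land(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    """Land mask: drop the lowest quantile of a smoothed random field."""
    shape = spec.geometry.fine_shape
    if spec.water_fraction == 0:
        return np.ones(shape, bool)
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=max(shape) / 8)
    threshold = np.quantile(field, spec.water_fraction)
    land = field > threshold
    if not land.any():
        land[shape[0] // 2, shape[1] // 2] = True
    return land


def _make_countries(spec: SynthSpec, land: np.ndarray, rng: np.random.Generator) -> CountryRaster:
    """Nearest-seed partition of land pixels into country ids 1..n."""
    geom = spec.geometry
    land_idx = np.argwhere(land)
    seeds = land_idx[rng.choice(len(land_idx), size=spec.n_countries, replace=False)]
    rows, cols = np.indices(geom.fine_shape)
    d2 = (rows[..., None] - seeds[:, 0]) ** 2 + (cols[..., None] - seeds[:, 1]) ** 2
    ids = (np.argmin(d2, axis=-1) + 1).astype(np.int32)
    ids[~land] = 0
    return CountryRaster(geom, ids, land.copy())


def _make_population(
    spec: SynthSpec, countries: CountryRaster, rng: np.random.Generator
) -> FineGrid:
    """Gaussian city bumps plus background, renormalised per country."""
    geom = spec.geometry
    rows, cols = np.indices(geom.fine_shape)
    density = np.full(geom.fine_shape, 0.05)
    sigma = geom.refinement / 4.0
    for cid in countries.country_ids():
        pix = np.argwhere((countries.ids == cid) & countries.valid_mask)
        n_clusters = min(spec.clusters_per_country, len(pix))
        centers = pix[rng.choice(len(pix), size=n_clusters, replace=False)]
        for cr, cc in centers:
            amp = 10.0 ** rng.uniform(1.0, 2.0)
            density += amp * np.exp(-((rows - cr) ** 2 + (cols - cc) ** 2) / (2 * sigma**2))
    values = np.where(countries.valid_mask, density, 0.0)
    for cid in countries.country_ids():
        sel = (countries.ids == cid) & countries.valid_mask
        values[sel] *= spec.country_total(int(cid)) / values[sel].sum()
    return FineGrid(geom, values, countries.valid_mask.copy())


def _make_roads(spec: SynthSpec, countries: CountryRaster, rng: np.random.Generator) -> list:
    """Polylines linking the population-weighted country extents.

    The main trunk road joins the per-country mean pixel centers in
    country-id order, so it crosses every country; a second jittered road
    adds some network texture.
    """
    geom = spec.geometry
    lon, lat = pixel_center_arrays(geom)
    waypoints = []
    for cid in countries.country_ids():
        sel = (countries.ids == cid) & countries.valid_mask
        waypoints.append((lon[sel].mean(), lat[sel].mean()))
    if len(waypoints) == 1:
        # single-country world still needs a polyline with two vertices
        (x, y) = waypoints[0]
        waypoints.append((x + geom.coarse_cell_size, y))
    roads = [shapely.LineString(waypoints)]
    jitter = geom.coarse_cell_size * 0.3
    wobble = [(x + rng.uniform(-jitter, jitter), y + rng.uniform(-jitter, jitter)) for x, y in waypoints]
    if len(wobble) >= 2:
        roads.append(shapely.LineString(wobble))
    return roads


def _make_urban_fractions(
    spec: SynthSpec, baseline: FineGrid, rng: np.random.Generator
) -> dict[int, CoarseGrid]:
    """Coarse fractions proportional to baseline cell population, drifting up."""
    geom = spec.geometry
    r = geom.refinement
    cell_pop = np.where(baseline.valid_mask, baseline.values, 0.0)
    cell_pop = cell_pop.reshape(geom.n_coarse_rows, r, geom.n_coarse_cols, r).sum(axis=(1, 3))
    cell_valid = baseline.valid_mask.reshape(geom.n_coarse_rows, r, geom.n_coarse_cols, r).any(axis=(1, 3))
    total = cell_pop.sum()
    rel = cell_pop / total if total > 0 else np.zeros_like(cell_pop)
    base = rel / rel.max() * 2 * spec.urban_fraction_mean_start if rel.max() > 0 else rel
    fractions = {}
    for year in spec.years:
        t = year - spec.year_start
        values = np.clip(base + spec.urban_fraction_annual_increment * t, 0.0, 1.0)
        values[~cell_valid] = 0.0
        fractions[year] = CoarseGrid(geom, values, cell_valid.copy())
    return fractions


def _make_series(spec: SynthSpec) -> ScenarioSeries:
    """Five-year-step country trajectories anchored at the baseline totals."""
    rows = []
    step_years = list(range(spec.year_start, spec.year_end + 1, spec.series_step))
    if step_years[-1] != spec.year_end:
        step_years.append(spec.year_end)
    for cid in range(1, spec.n_countries + 1):
        for year in step_years:
            t = year - spec.year_start
            total = spec.country_total(cid) * (1 + spec.annual_growth_rate) ** t
            share = min(1.0, max(0.0, spec.urban_share_start + spec.urban_share_annual_increment * t))
            rows.append((cid, year, total, share))
    return ScenarioSeries(
        pd.DataFrame(rows, columns=["country_id", "year", "total_population", "urban_share"])
    )


def generate_world(spec: SynthSpec) -> SynthWorld:
    """Build a complete, internally consistent synthetic world from a spec.

    Guarantees: country baseline sums match the specified totals exactly,
    fractions and shares stay in [0, 1], at least one road crosses every
    country, and identical seeds give identical worlds.
    """
    rng = np.random.default_rng(spec.seed)
    land = _make_land(spec, rng)
    countries = _make_countries(spec, land, rng)
    baseline = _make_population(spec, countries, rng)
    roads = _make_roads(spec, countries, rng)
    fractions = _make_urban_fractions(spec, baseline, rng)
    series = _make_series(spec)
    return SynthWorld(spec, baseline, countries, roads, fractions, series, DEFAULT_SCENARIO_MATRIX)


def worked_example_world() -> SynthWorld:
    """Tiny fixed world: 2x2 coarse cells, refinement 3, 2 countries, no water.

    Small enough (36 fine pixels) that urban masks and allotments can be
    verified by hand and by brute-force subset enumeration.  Country 1 is
    the western half, country 2 the eastern half; population is a fixed
    integer pattern with deliberate ties.
    """
    spec = SynthSpec(
        n_coarse_rows=2, n_coarse_cols=2, refinement=3, n_countries=2,
        water_fraction=0.0, year_start=2000, year_end=2005, seed=0,
        baseline_total_per_country=120.0,
    )
    geom = spec.geometry
    # 6x6 fixed population; note the repeated values (ties) in each block
    pop = np.array(
        [
            [9, 1, 1, 2, 2, 7],
            [1, 5, 1, 2, 8, 2],
            [1, 1, 3, 4, 2, 2],
            [6, 1, 0, 0, 3, 3],
            [1, 4, 0, 5, 1, 3],
            [2, 2, 1, 1, 1, 6],
        ],
        dtype=float,
    )
    land = np.ones((6, 6), bool)
    ids = np.where(np.arange(6)[None, :] < 3, 1, 2).astype(np.int32) * np.ones((6, 1), np.int32)
    countries = CountryRaster(geom, ids, land)
    values = pop.copy()
    for cid in (1, 2):
        sel = ids == cid
        values[sel] *= spec.baseline_total_per_country / values[sel].sum()
    baseline = FineGrid(geom, values, land.copy())
    roads = [shapely.LineString([
        (geom.origin_lon, geom.origin_lat - 3.5 * geom.fine_cell_size),
        (geom.origin_lon + 6 * geom.fine_cell_size, geom.origin_lat - 2.5 * geom.fine_cell_size),
    ])]
    fractions = {
        year: CoarseGrid(
            geom,
            np.clip(np.array([[0.5, 0.25], [0.25, 0.5]]) + 0.01 * (year - 2000), 0, 1),
            np.ones((2, 2), bool),
        )
        for year in spec.years
    }
    rows = []
    for cid in (1, 2):
        for year in (2000, 2005):
            t = year - 2000
            rows.append((cid, year, 120.0 * (1.02**t), 0.4 + 0.01 * t))
    series = ScenarioSeries(
        pd.DataFrame(rows, columns=["country_id", "year", "total_population", "urban_share"])
    )
    return SynthWorld(spec, baseline, countries, roads, fractions, series, DEFAULT_SCENARIO_MATRIX)
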