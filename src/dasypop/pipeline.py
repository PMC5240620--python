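"""End-to-end orchestration: baseline preparation and multi-scenario runs."""

from __future__ import annotations

import logging
from pathlib import Path

from .allotment import ProjectionRun, annualize, project_scenario, select_scenarios
from .core_grids import CountryRaster, FineGrid
from .io_formats import output_name, write_raster
from .ranking import (
    RESCALE_HI,
    RESCALE_LO,
    UniquePopulation,
    compute_cogs,
    distance_to_cog,
    distance_to_roads,
    inverse_rescale,
    make_unique_population,
)
from .synthetic import SynthWorld

__all__ = ["prepare_unique_population", "run_world", "run_world_all_scenarios", "write_run"]

logger = logging.getLogger(__name__)


def prepare_unique_population(
    baseline: FineGrid, roads, lo: float = RESCALE_LO, hi: float = RESCALE_HI
) -> UniquePopulation:
    """Baseline preparation: both perturbation layers added to the population.

    Computes the distance-to-roads and distance-to-COG layers on the
    baseline grid, rescales each into [lo, hi], and adds them, producing
    the tie-free surface that seeds the annual loop.
    """
    geom = baseline.geometry
    road_layer = distance_to_roads(roads, geom, baseline.valid_mask)
    cog_layer = distance_to_cog(compute_cogs(baseline), geom, baseline.valid_mask)
    inv_road = inverse_rescale(road_layer, lo, hi)
    inv_cog = inverse_rescale(cog_layer, lo, hi)
    return make_unique_population(baseline, inv_road, inv_cog)


def run_world(
    world: SynthWorld,
    scenario: tuple[int, str] = (1, "4.5"),
    years: range | None = None,
) -> ProjectionRun:
    """Project one scenario over a synthetic world.

    The world carries a single urban-fraction series and a single country
    series, so the scenario label only tags the run; annualization fills
    in the years between the series' five-year steps.
    """
    years = years if years is not None else world.spec.years
    unique = prepare_unique_population(world.baseline, world.roads)
    series = annualize(world.series, years)
    return project_scenario(
        unique, world.urban_fractions, world.countries, series, years, scenario=scenario
    )


def run_world_all_scenarios(world: SynthWorld, years: range | None = None) -> list[ProjectionRun]:
    """Project every positive-probability scenario combination over a world."""
    return [run_world(world, scenario, years) for scenario in select_scenarios(world.matrix)]


def write_run(run: ProjectionRun, out_dir, nodata: float = -9999.0) -> list[Path]:
    """Write one raster per year, named ``ssp<al>_rcp<al>_<year>.tif``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ssp, rcp = run.scenario
    paths = []
    for year in run.years:
        path = out_dir / output_name(ssp, rcp, year)
        write_raster(run.grids[year], path, nodata=nodata)
        paths.append(path)
    return paths
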