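"""Mass-conserving allotment of country scenario populations and the annual loop.

Each year, every country's scenario population is split into an urban
part ``U = total * urban_share`` and a rural part ``L = total - U`` and
distributed over the country's urban and rural pixel strata (the strata
are defined by the current year's urban mask intersected with the country
raster).  Within a stratum each pixel receives its proportional share of
the stratum target, weighted by its previous-year population, so pairwise
pixel ratios are preserved inside every (country, stratum) set and each
country's grid total equals its scenario total exactly.

The annual loop couples this to the ranking step: the year-2000 urban
mask and weights come from the tie-free unique population; every later
year ranks the previous year's output grid (row-major index re-breaking
any exact ties) against that year's urban-fraction grid, then re-allots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_grids import CoarseGrid, CountryRaster, FineGrid
from .ranking import UniquePopulation, UrbanMask, build_urban_mask

__all__ = [
    "ScenarioSeries",
    "ScenarioMatrix",
    "ProjectionRun",
    "DEFAULT_SCENARIO_MATRIX",
    "select_scenarios",
    "annualize",
    "allot_population",
    "project_scenario",
]

logger = logging.getLogger(__name__)

RCP_LABELS = ("2.6", "4.5", "6.0", "8.5")
SSP_IDS = (1, 2, 3, 4, 5)


@dataclass
class ScenarioSeries:
    """Per-country, per-year total population and urban share.

    Backed by a DataFrame with columns ``country_id, year,
    total_population, urban_share``; invariants (totals >= 0, shares in
    [0, 1], no duplicate keys) are enforced at construction.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"country_id", "year", "total_population", "urban_share"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"scenario series missing columns: {sorted(missing)}")
        t = self.table.copy()
        t["country_id"] = t["country_id"].astype(int)
        t["year"] = t["year"].astype(int)
        for i, row in t.iterrows():
            if row.total_population < 0:
                raise ValueError(f"row {i}: negative total_population {row.total_population}")
            if not (0 <= row.urban_share <= 1):
                raise ValueError(f"row {i}: urban_share {row.urban_share} outside [0, 1]")
        if t.duplicated(["country_id", "year"]).any():
            raise ValueError("duplicate (country_id, year) entries")
        self.table = t.sort_values(["country_id", "year"]).reset_index(drop=True)
        self._by_key = {
            (int(r.country_id), int(r.year)): (float(r.total_population), float(r.urban_share))
            for r in self.table.itertuples()
        }

    def countries(self) -> list[int]:
        return sorted(self.table["country_id"].unique().tolist())

    def years(self) -> list[int]:
        return sorted(self.table["year"].unique().tolist())

    def get(self, country_id: int, year: int) -> tuple[float, float]:
        """(total_population, urban_share) for one country-year."""
        try:
            return self._by_key[(int(country_id), int(year))]
        except KeyError:
            raise KeyError(f"no scenario entry for country {country_id}, year {year}") from None

    def has(self, country_id: int, year: int) -> bool:
        return (int(country_id), int(year)) in self._by_key


@dataclass(frozen=True)
class ScenarioMatrix:
    """SSP x RCP plausibility matrix; probabilities in [0, 1]."""

    probability: dict[tuple[int, str], float]

    def __post_init__(self) -> None:
        for ssp in SSP_IDS:
            for rcp in RCP_LABELS:
                p = self.probability.get((ssp, rcp))
                if p is None:
                    raise ValueError(f"matrix entry missing for SSP{ssp}-RCP{rcp}")
                if not (0 <= p <= 1):
                    raise ValueError(f"probability {p} for SSP{ssp}-RCP{rcp} outside [0, 1]")


# SSP-RCP plausibility matrix used for scenario inclusion (probabilities
# as published; zero marks implausible combinations such as SSP1-RCP8.5).
DEFAULT_SCENARIO_MATRIX = ScenarioMatrix(
    {
        (1, "2.6"): 0.09, (1, "4.5"): 0.45, (1, "6.0"): 0.45, (1, "8.5"): 0.00,
        (2, "2.6"): 0.00, (2, "4.5"): 0.09, (2, "6.0"): 0.68, (2, "8.5"): 0.23,
        (3, "2.6"): 0.00, (3, "4.5"): 0.17, (3, "6.0"): 0.50, (3, "8.5"): 0.33,
        (4, "2.6"): 0.00, (4, "4.5"): 0.37, (4, "6.0"): 0.56, (4, "8.5"): 0.07,
        (5, "2.6"): 0.00, (5, "4.5"): 0.07, (5, "6.0"): 0.37, (5, "8.5"): 0.56,
    }
)


def select_scenarios(matrix: ScenarioMatrix) -> list[tuple[int, str]]:
    """All (SSP, RCP) pairs with positive probability, in SSP-major order."""
    return [
        (ssp, rcp)
        for ssp in SSP_IDS
        for rcp in RCP_LABELS
        if matrix.probability[(ssp, rcp)] > 0
    ]


def annualize(series: ScenarioSeries, years: range) -> ScenarioSeries:
    """Linearly interpolate a coarse-step series to annual resolution.

    Provided time points are reproduced exactly; requesting a year outside
    a country's provided span is an error (no extrapolation).
    """
    rows = []
    target = np.asarray(list(years), dtype=float)
    for cid, grp in series.table.groupby("country_id"):
        yrs = grp["year"].to_numpy(dtype=float)
        if len(yrs) < 2:
            raise ValueError(f"country {cid}: need >= 2 time points to annualize")
        if target.min() < yrs.min() or target.max() > yrs.max():
            raise ValueError(
                f"country {cid}: requested years [{years.start}, {years.stop - 1}] "
                f"outside provided span [{int(yrs.min())}, {int(yrs.max())}]"
            )
        totals = np.interp(target, yrs, grp["total_population"].to_numpy(dtype=float))
        shares = np.interp(target, yrs, grp["urban_share"].to_numpy(dtype=float))
        for y, tot, sh in zip(target.astype(int), totals, shares):
            rows.append((int(cid), int(y), tot, sh))
    return ScenarioSeries(
        pd.DataFrame(rows, columns=["country_id", "year", "total_population", "urban_share"])
    )


def allot_population(
    prev_pop: FineGrid,
    mask: UrbanMask,
    countries: CountryRaster,
    series: ScenarioSeries,
    year: int,
) -> FineGrid:
    """Distribute one year's country populations over the (country, stratum) pixels.

    Within each stratum, pixel i receives ``target * w_i / sum(w)`` with
    weights w taken from ``prev_pop``, so previous-year pixel ratios are
    preserved.  A stratum whose weights sum to zero but whose target is
    positive receives uniform shares; a stratum with no pixels at all
    hands its target to the country's other stratum so no population is
    ever lost.  Countries on the raster but absent from the series are a
    hard error; series countries absent from the raster are skipped with a
    warning.
    """
    geom = prev_pop.geometry
    for other, name in ((mask.grid, "mask"), (countries, "countries")):
        if other.geometry != geom:
            raise ValueError(f"{name} geometry does not match population geometry")
    prev_pop.require_nonnegative()

    valid = prev_pop.valid_mask & countries.valid_mask
    urban = mask.urban
    out = np.zeros(geom.fine_shape, dtype=np.float64)
    present = set(int(c) for c in np.unique(countries.ids[valid]))
    for cid in sorted(present):
        if not series.has(cid, year):
            raise KeyError(f"country {cid} present on the raster has no series entry for {year}")
    for cid in series.countries():
        if cid not in present and series.has(cid, year):
            logger.warning("country %d in the scenario series has no raster pixels; skipped", cid)

    for cid in sorted(present):
        total, share = series.get(cid, year)
        in_country = valid & (countries.ids == cid)
        strata = {
            "urban": (in_country & urban, total * share),
            "rural": (in_country & ~urban, total - total * share),
        }
        # a stratum with zero pixels hands its target to the other one
        n_urban = int(strata["urban"][0].sum())
        n_rural = int(strata["rural"][0].sum())
        if n_urban == 0 and strata["urban"][1] > 0:
            strata = {"rural": (strata["rural"][0], total)}
        elif n_rural == 0 and strata["rural"][1] > 0:
            strata = {"urban": (strata["urban"][0], total)}
        for sel, target in strata.values():
            n = int(sel.sum())
            if n == 0 or target == 0:
                continue
            w = prev_pop.values[sel]
            wsum = w.sum()
            if wsum > 0:
                out[sel] = target * w / wsum
            else:
                out[sel] = target / n
    return FineGrid(geom, out, prev_pop.valid_mask.copy())


@dataclass
class ProjectionRun:
    """One scenario's annual output grids, keyed by year."""

    scenario: tuple[int, str]
    years: range
    grids: dict[int, FineGrid] = field(default_factory=dict)


def project_scenario(
    baseline_unique: UniquePopulation,
    urban_fractions: dict[int, CoarseGrid],
    countries: CountryRaster,
    series: ScenarioSeries,
    years: range,
    scenario: tuple[int, str] = (0, "none"),
    progress: bool = True,
) -> ProjectionRun:
    """Iterate mask-building and allotment over an inclusive year range.

    The first year's mask and weights come from the unique population (the
    perturbation layers are added once, at baseline); each later year
    ranks the previous year's output grid, whose residual exact ties are
    broken by row-major index, against that year's urban fractions.  Every
    published year is a scenario-consistent redistribution, so mass
    conservation holds for all of them.  Missing years in either input are
    reported before any computation starts.
    """
    missing_f = [y for y in years if y not in urban_fractions]
    if missing_f:
        raise ValueError(f"urban fractions missing for years {missing_f}")
    present = countries.country_ids()
    missing_s = [
        (int(c), y) for y in years for c in present if not series.has(int(c), y)
    ]
    if missing_s:
        raise ValueError(f"scenario series missing entries: {missing_s[:5]}...")

    run = ProjectionRun(scenario=scenario, years=years)
    current = baseline_unique
    for year in years:
        mask = build_urban_mask(current, urban_fractions[year].require_fraction())
        grid = allot_population(current.grid, mask, countries, series, year)
        run.grids[year] = grid
        if progress:
            _log_conservation(grid, countries, series, year)
        current = UniquePopulation(grid)
    return run


def _log_conservation(grid: FineGrid, countries: CountryRaster, series: ScenarioSeries, year: int) -> None:
    valid = grid.valid_mask & countries.valid_mask
    worst = 0.0
    for cid in countries.country_ids():
        total, _ = series.get(int(cid), year)
        got = float(grid.values[valid & (countries.ids == cid)].sum())
        if total > 0:
            worst = max(worst, abs(got - total) / total)
    logger.info("year %d allotted; worst country conservation residual %.3e", year, worst)
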