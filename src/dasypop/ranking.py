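"""Tie-free population ranking and the per-cell urban mask.

Classifying fine pixels as urban requires a strict ranking of pixel
values inside every coarse cell, but raw population grids are full of
ties (zeros over empty land, repeated small counts).  The surface that is
actually ranked -- the *unique population* -- is the population plus two
tiny perturbation layers: the rescaled inverse distance to the nearest
road and the rescaled inverse distance to the coarse cell's population
center of gravity (COG).  Each perturbation layer is affinely rescaled to
[1.0e-5, 1.1e-5] people, so their sum can never exceed 2.2e-5 and cannot
reorder pixels whose populations differ by more than that; it only breaks
ties, favouring pixels near roads and near existing population centers.
Residual exact collisions are resolved deterministically by row-major
pixel index, giving a strict total order within every coarse cell.

The urban mask for a year is then obtained per coarse cell by selecting
the top-k ranked valid pixels, where k is the cell's urban fraction times
the pixel count, rounded half away from zero ("nearest integer") and
capped at the number of valid (land) pixels in the cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely

from .core_grids import (
    CoarseGrid,
    CountryRaster,
    FineGrid,
    GridGeometry,
    block_of,
    coarse_cell_center,
    pixel_center_arrays,
)

__all__ = [
    "DistanceLayer",
    "UniquePopulation",
    "UrbanMask",
    "distance_to_roads",
    "compute_cogs",
    "distance_to_cog",
    "inverse_rescale",
    "make_unique_population",
    "build_urban_mask",
    "round_half_away",
]

# Default perturbation bounds, in people per pixel.
RESCALE_LO = 1.0e-5
RESCALE_HI = 1.1e-5


@dataclass
class DistanceLayer:
    """Fine grid of planar Euclidean distances in degrees, >= 0 and finite."""

    grid: FineGrid

    def __post_init__(self) -> None:
        v = self.grid.values[self.grid.valid_mask]
        if v.size and (not np.all(np.isfinite(v)) or v.min() < 0):
            raise ValueError("distances must be finite and non-negative")


@dataclass
class UniquePopulation:
    """Population surface carrying a strict per-coarse-cell pixel order.

    ``order`` ranks pixels by value descending with row-major index
    ascending as the tie-break, so the induced ranking is a strict total
    order even where values collide exactly.
    """

    grid: FineGrid

    def ranking_keys(self) -> np.ndarray:
        """Flat row-major indices sorted by (value desc, index asc)."""
        flat = self.grid.values.ravel()
        # stable sort of -value preserves row-major order among exact ties
        return np.argsort(-flat, kind="stable")


@dataclass
class UrbanMask:
    """Boolean fine-lattice urban classification; urban implies valid."""

    grid: FineGrid

    @property
    def urban(self) -> np.ndarray:
        return self.grid.values.astype(bool) & self.grid.valid_mask

    def urban_count(self) -> int:
        return int(self.urban.sum())


def distance_to_roads(roads, geometry: GridGeometry, valid_mask=None) -> DistanceLayer:
    """Planar Euclidean distance (degrees) from each pixel center to the road network.

    Parameters
    ----------
    roads
        Iterable of polylines: shapely LineStrings or coordinate sequences
        ``[(lon, lat), ...]`` with at least two vertices each.
    geometry
        Fine lattice on which to evaluate distances.
    valid_mask
        Domain (land) mask to attach to the layer; defaults to all pixels.
        The mask defines the domain over which a later rescale finds its
        extremes.

    Distances are computed in raw lon/lat degree space with no
    great-circle correction, matching simple raster distance tooling; the
    distortion is documented rather than corrected.
    """
    lines = []
    for road in roads:
        if not isinstance(road, shapely.LineString):
            if len(road) < 2:
                raise ValueError("each road polyline needs at least two vertices")
            road = shapely.LineString(road)
        if len(road.coords) < 2:
            raise ValueError("each road polyline needs at least two vertices")
        lines.append(road)
    if not lines:
        raise ValueError("empty road set: the road perturbation layer would be undefined")
    network = shapely.union_all(lines)
    lon, lat = pixel_center_arrays(geometry)
    points = shapely.points(lon.ravel(), lat.ravel())
    dist = shapely.distance(points, network).reshape(geometry.fine_shape)
    mask = np.ones(geometry.fine_shape, bool) if valid_mask is None else np.asarray(valid_mask, bool)
    return DistanceLayer(FineGrid(geometry, dist, mask.copy()))


def compute_cogs(pop: FineGrid, geometry: GridGeometry | None = None) -> np.ndarray:
    """Population-weighted center of gravity of every coarse cell.

    Returns an array of shape ``(n_coarse_rows, n_coarse_cols, 2)`` holding
    (lon, lat).  Cells whose valid-pixel population sums to zero (or that
    contain no valid pixel) fall back to the cell's geometric center, so a
    COG is defined for every cell.
    """
    geometry = geometry or pop.geometry
    pop.require_nonnegative()
    lon, lat = pixel_center_arrays(geometry)
    cogs = np.empty((geometry.n_coarse_rows, geometry.n_coarse_cols, 2))
    for cr in range(geometry.n_coarse_rows):
        for cc in range(geometry.n_coarse_cols):
            rows, cols = block_of(geometry, cr, cc)
            m = pop.valid_mask[rows, cols]
            w = pop.values[rows, cols][m]
            if m.any() and w.sum() > 0:
                cogs[cr, cc, 0] = np.average(lon[rows, cols][m], weights=w)
                cogs[cr, cc, 1] = np.average(lat[rows, cols][m], weights=w)
            else:
                cogs[cr, cc] = coarse_cell_center(geometry, cr, cc)
    return cogs


def distance_to_cog(cogs: np.ndarray, geometry: GridGeometry, valid_mask=None) -> DistanceLayer:
    """Distance from each pixel center to the COG of its own coarse cell."""
    if cogs.shape != (geometry.n_coarse_rows, geometry.n_coarse_cols, 2):
        raise ValueError(f"COG table shape {cogs.shape} does not match geometry")
    if not np.all(np.isfinite(cogs)):
        raise ValueError("COG table contains undefined entries")
    lon, lat = pixel_center_arrays(geometry)
    r = geometry.refinement
    cog_lon = np.repeat(np.repeat(cogs[:, :, 0], r, axis=0), r, axis=1)
    cog_lat = np.repeat(np.repeat(cogs[:, :, 1], r, axis=0), r, axis=1)
    dist = np.hypot(lon - cog_lon, lat - cog_lat)
    mask = np.ones(geometry.fine_shape, bool) if valid_mask is None else np.asarray(valid_mask, bool)
    return DistanceLayer(FineGrid(geometry, dist, mask.copy()))


def inverse_rescale(
    dist: DistanceLayer, lo: float = RESCALE_LO, hi: float = RESCALE_HI
) -> FineGrid:
    """Invert a distance layer and affinely rescale it into [lo, hi].

    The inversion is ``v = 1 / (d + delta)`` with ``delta`` equal to one
    fine cell size, which is bounded at d = 0 (a pixel on a road) while
    strictly reversing the distance order.  A single affine map over the
    whole domain then sends min(v) -> lo and max(v) -> hi, so the nearest
    pixel to a feature receives exactly ``hi`` and the farthest exactly
    ``lo``.
    """
    if not (hi > lo > 0):
        raise ValueError("require hi > lo > 0")
    grid = dist.grid
    delta = grid.geometry.fine_cell_size
    v = 1.0 / (grid.values + delta)
    vv = v[grid.valid_mask]
    vmin, vmax = vv.min(), vv.max()
    if vmin == vmax:
        raise ValueError("all valid distances identical: rescaled ordering undefined")
    out = lo + (v - vmin) * (hi - lo) / (vmax - vmin)
    return FineGrid(grid.geometry, out, grid.valid_mask.copy())


def make_unique_population(
    pop: FineGrid, inv_road: FineGrid, inv_cog: FineGrid
) -> UniquePopulation:
    """Add the two rescaled perturbation layers to the population surface."""
    for other, name in ((inv_road, "inv_road"), (inv_cog, "inv_cog")):
        if other.geometry != pop.geometry:
            raise ValueError(f"{name} geometry does not match population geometry")
    pop.require_nonnegative()
    values = pop.values + inv_road.values + inv_cog.values
    values[~pop.valid_mask] = 0.0
    return UniquePopulation(FineGrid(pop.geometry, values, pop.valid_mask.copy()))


def round_half_away(x) -> np.ndarray:
    """Round to nearest integer, halves away from zero (not banker's)."""
    x = np.asarray(x, dtype=np.float64)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(np.int64)


def build_urban_mask(unique_pop: UniquePopulation, urban_fraction: CoarseGrid) -> UrbanMask:
    """Select the top-ranked pixels of every coarse cell as urban.

    Per coarse cell the target count is ``round_half_away(fraction * R^2)``
    -- the fraction refers to total cell area, so the full pixel count is
    used -- capped at the number of valid (land) pixels so water is never
    urbanized.  Exactly ``min(k, n_valid)`` pixels are marked urban: the
    top-k under the strict (value desc, row-major index asc) order.
    """
    geometry = unique_pop.grid.geometry
    if urban_fraction.geometry != geometry:
        raise ValueError("urban fraction geometry does not match unique population")
    frac = urban_fraction.values
    fmask = urban_fraction.valid_mask
    if fmask.any():
        fv = frac[fmask]
        if fv.min() < 0 or fv.max() > 1:
            raise ValueError("urban fraction outside [0, 1] on a valid cell")
    r2 = geometry.refinement**2
    urban = np.zeros(geometry.fine_shape, dtype=bool)
    vmask = unique_pop.grid.valid_mask
    values = unique_pop.grid.values
    for cr in range(geometry.n_coarse_rows):
        for cc in range(geometry.n_coarse_cols):
            if not fmask[cr, cc]:
                continue
            rows, cols = block_of(geometry, cr, cc)
            cell_valid = vmask[rows, cols]
            n_valid = int(cell_valid.sum())
            if n_valid == 0:
                continue
            k = min(int(round_half_away(frac[cr, cc] * r2)), n_valid)
            if k == 0:
                continue
            cell_vals = values[rows, cols].ravel()
            order = np.argsort(-cell_vals, kind="stable")  # value desc, index asc
            order = order[cell_valid.ravel()[order]]
            block_urban = np.zeros(cell_vals.size, dtype=bool)
            block_urban[order[:k]] = True
            urban[rows, cols] = block_urban.reshape(cell_valid.shape)
    return UrbanMask(FineGrid(geometry, urban.astype(np.float64), vmask.copy()))
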