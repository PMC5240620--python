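"""Georeferenced grid types and the fine/coarse nesting contract.

Every raster in the pipeline lives on one of two nested regular
longitude/latitude lattices: a *fine* lattice (population, distances,
country ids) and a *coarse* lattice (urban fractions) whose cells each
cover an exact R x R block of fine pixels.  The convention throughout is
north-up and row-major: row 0 is the northernmost row, ``origin_lon`` /
``origin_lat`` name the top-left corner of pixel (0, 0), and all index
spans are half-open, 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GridGeometry",
    "FineGrid",
    "CoarseGrid",
    "CountryRaster",
    "block_of",
    "pixel_center",
    "pixel_of",
    "coarse_cell_center",
]


@dataclass(frozen=True)
class GridGeometry:
    """Shared geometry of a nested fine/coarse lattice pair.

    Parameters
    ----------
    origin_lon, origin_lat
        Geographic coordinates (degrees) of the top-left corner of fine
        pixel (0, 0).  Latitude decreases with increasing row index.
    fine_cell_size
        Side length of a fine pixel in degrees (1/120 deg = 30 arc-seconds
        for the published African dataset).
    refinement
        Number of fine pixels per coarse-cell side (60 nests 30 arc-second
        pixels inside 0.5-degree cells).
    n_fine_rows, n_fine_cols
        Fine lattice shape; each must be divisible by ``refinement`` so
        coarse cells tile the domain exactly.
    """

    origin_lon: float
    origin_lat: float
    fine_cell_size: float
    refinement: int
    n_fine_rows: int
    n_fine_cols: int

    def __post_init__(self) -> None:
        if self.fine_cell_size <= 0:
            raise ValueError("fine_cell_size must be positive")
        if self.refinement < 1:
            raise ValueError("refinement must be an integer >= 1")
        if self.n_fine_rows % self.refinement or self.n_fine_cols % self.refinement:
            raise ValueError(
                f"fine shape ({self.n_fine_rows}, {self.n_fine_cols}) is not "
                f"divisible by refinement {self.refinement}"
            )

    @property
    def coarse_cell_size(self) -> float:
        return self.refinement * self.fine_cell_size

    @property
    def n_coarse_rows(self) -> int:
        return self.n_fine_rows // self.refinement

    @property
    def n_coarse_cols(self) -> int:
        return self.n_fine_cols // self.refinement

    @property
    def fine_shape(self) -> tuple[int, int]:
        return (self.n_fine_rows, self.n_fine_cols)

    @property
    def coarse_shape(self) -> tuple[int, int]:
        return (self.n_coarse_rows, self.n_coarse_cols)


def block_of(geometry: GridGeometry, coarse_row: int, coarse_col: int) -> tuple[slice, slice]:
    """Half-open R x R fine-index block covered by one coarse cell.

    Blocks over all coarse cells partition the fine lattice exactly.
    """
    if not (0 <= coarse_row < geometry.n_coarse_rows):
        raise IndexError(f"coarse_row {coarse_row} out of range [0, {geometry.n_coarse_rows})")
    if not (0 <= coarse_col < geometry.n_coarse_cols):
        raise IndexError(f"coarse_col {coarse_col} out of range [0, {geometry.n_coarse_cols})")
    r = geometry.refinement
    return (
        slice(coarse_row * r, (coarse_row + 1) * r),
        slice(coarse_col * r, (coarse_col + 1) * r),
    )


def pixel_center(geometry: GridGeometry, row: int, col: int) -> tuple[float, float]:
    """Geographic (lon, lat) center of a fine pixel, north-up row-major."""
    if not (0 <= row < geometry.n_fine_rows):
        raise IndexError(f"row {row} out of range [0, {geometry.n_fine_rows})")
    if not (0 <= col < geometry.n_fine_cols):
        raise IndexError(f"col {col} out of range [0, {geometry.n_fine_cols})")
    cs = geometry.fine_cell_size
    return (geometry.origin_lon + (col + 0.5) * cs, geometry.origin_lat - (row + 0.5) * cs)


def pixel_of(geometry: GridGeometry, lon: float, lat: float) -> tuple[int, int]:
    """Fine (row, col) of the pixel containing a geographic point.

    Inverse of :func:`pixel_center` for in-domain points; points on a
    shared pixel edge belong to the pixel south/east of the edge.
    """
    cs = geometry.fine_cell_size
    col = int(np.floor((lon - geometry.origin_lon) / cs))
    row = int(np.floor((geometry.origin_lat - lat) / cs))
    if not (0 <= row < geometry.n_fine_rows and 0 <= col < geometry.n_fine_cols):
        raise IndexError(f"point ({lon}, {lat}) outside the grid extent")
    return row, col


def coarse_cell_center(geometry: GridGeometry, coarse_row: int, coarse_col: int) -> tuple[float, float]:
    """Geographic (lon, lat) center of a coarse cell."""
    rows, cols = block_of(geometry, coarse_row, coarse_col)
    cs = geometry.coarse_cell_size
    return (
        geometry.origin_lon + (coarse_col + 0.5) * cs,
        geometry.origin_lat - (coarse_row + 0.5) * cs,
    )


def pixel_center_arrays(geometry: GridGeometry) -> tuple[np.ndarray, np.ndarray]:
    """(lon, lat) center coordinates of every fine pixel as 2-D arrays."""
    cs = geometry.fine_cell_size
    lon = geometry.origin_lon + (np.arange(geometry.n_fine_cols) + 0.5) * cs
    lat = geometry.origin_lat - (np.arange(geometry.n_fine_rows) + 0.5) * cs
    return np.broadcast_to(lon, geometry.fine_shape).copy(), np.broadcast_to(
        lat[:, None], geometry.fine_shape
    ).copy()


def _check_shape(values: np.ndarray, valid_mask: np.ndarray, shape: tuple[int, int], what: str) -> None:
    if values.shape != shape:
        raise ValueError(f"{what} values shape {values.shape} != geometry shape {shape}")
    if valid_mask.shape != shape:
        raise ValueError(f"{what} valid_mask shape {valid_mask.shape} != geometry shape {shape}")


@dataclass
class FineGrid:
    """Fine-lattice raster of real values with a validity mask.

    Invalid pixels (water / outside the domain) are never read by any
    algorithm and serialize as the nodata sentinel.  Population grids must
    be non-negative on valid pixels; use :meth:`require_nonnegative`.
    """

    geometry: GridGeometry
    values: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        _check_shape(self.values, self.valid_mask, self.geometry.fine_shape, "FineGrid")

    def require_nonnegative(self) -> "FineGrid":
        if np.any(self.values[self.valid_mask] < 0):
            raise ValueError("negative values on valid pixels")
        return self

    def copy_with(self, values: np.ndarray) -> "FineGrid":
        return FineGrid(self.geometry, np.array(values, dtype=np.float64), self.valid_mask.copy())

    def valid_sum(self) -> float:
        return float(self.values[self.valid_mask].sum())


@dataclass
class CoarseGrid:
    """Coarse-lattice raster (urban fractions) sharing geometry with nested fine grids."""

    geometry: GridGeometry
    values: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        _check_shape(self.values, self.valid_mask, self.geometry.coarse_shape, "CoarseGrid")

    def require_fraction(self) -> "CoarseGrid":
        v = self.values[self.valid_mask]
        if v.size and (v.min() < 0 or v.max() > 1):
            raise ValueError("urban fractions outside [0, 1] on valid cells")
        return self


@dataclass
class CountryRaster:
    """Fine-lattice integer country identifiers; invalid over water/outside."""

    geometry: GridGeometry
    ids: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        if not np.issubdtype(self.ids.dtype, np.integer):
            raise ValueError("country ids must be integers")
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        _check_shape(self.ids, self.valid_mask, self.geometry.fine_shape, "CountryRaster")
        if self.valid_mask.any() and self.ids[self.valid_mask].min() < 0:
            raise ValueError("country ids must be non-negative")

    def country_ids(self) -> np.ndarray:
        """Sorted array of distinct ids present on valid pixels."""
        return np.unique(self.ids[self.valid_mask])
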