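"""File formats: GeoTIFF rasters, GeoJSON vectors, scenario CSVs, run config.

Rasters follow the published conventions: single-band 32-bit float
GeoTIFF (FLT4S), nodata -9999, plain longitude/latitude referencing on
the WGS84 datum, north-up with the tiepoint at the top-left corner.  The
geo-referencing is written and read directly through the GeoTIFF tags
(ModelPixelScale, ModelTiepoint, GeoKeyDirectory, GDAL_NODATA), so files
interoperate with GDAL-based stacks.

Vector inputs (road polylines, country border polygons) are GeoJSON;
scenario series and the SSP-RCP matrix are CSV.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import tifffile
import yaml
from shapely.geometry import mapping as shapely_mapping
from shapely.geometry import shape as shapely_shape

from .allotment import RCP_LABELS, SSP_IDS, ScenarioMatrix, ScenarioSeries
from .core_grids import CoarseGrid, CountryRaster, FineGrid, GridGeometry, pixel_center_arrays

__all__ = [
    "NODATA",
    "RunConfig",
    "read_raster",
    "write_raster",
    "rasterize_countries",
    "read_scenario_csv",
    "read_matrix_csv",
    "read_roads_geojson",
    "write_roads_geojson",
    "read_borders_geojson",
    "write_borders_geojson",
    "output_name",
]

logger = logging.getLogger(__name__)

NODATA = -9999.0

# GeoTIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GEO_KEY_DIRECTORY = 34735
_GDAL_NODATA = 42113

# GeoKeyDirectory for geographic WGS84 (EPSG:4326), PixelIsArea
_WGS84_GEOKEYS = (1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 1, 2048, 0, 1, 4326)


@dataclass
class RunConfig:
    """Projection run configuration; defaults match the published dataset.

    ``urban_fraction_pattern`` is a path template with ``{rcp}`` and
    ``{year}`` placeholders; output files are named by
    :func:`output_name`.
    """

    baseline_raster: str = "baseline_population.tif"
    urban_fraction_pattern: str = "urban_fraction_rcp{rcp}_{year}.tif"
    scenario_csv_pattern: str = "scenario_ssp{ssp}.csv"
    matrix_csv: str = "scenario_matrix.csv"
    roads_file: str = "roads.geojson"
    borders_file: str = "borders.geojson"
    countries_raster: str = ""  # pre-rasterized country ids; takes precedence over borders_file
    output_dir: str = "output"
    refinement: int = 60  # fine pixels per coarse-cell side (30 arc-sec in 0.5 deg)
    year_start: int = 2000
    year_end: int = 2100
    scenarios: list = field(default_factory=list)  # [] = all positive-probability pairs
    rescale_lo: float = 1.0e-5
    rescale_hi: float = 1.1e-5
    nodata: float = NODATA
    seed: int = 0  # synthetic-world generation only

    @property
    def years(self) -> range:
        return range(self.year_start, self.year_end + 1)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.scenarios = [tuple(s) if not isinstance(s, str) else _parse_scenario(s) for s in cfg.scenarios]
        return cfg

    def to_yaml(self, path) -> None:
        data = {k: getattr(self, k) for k in self.__dataclass_fields__}
        data["scenarios"] = [f"ssp{s}-rcp{r}" for s, r in self.scenarios]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _parse_scenario(text: str) -> tuple[int, str]:
    """Parse 'ssp2-rcp4.5' (case-insensitive) into (2, '4.5')."""
    t = text.lower().replace(" ", "")
    try:
        ssp_part, rcp_part = t.split("-")
        ssp = int(ssp_part.removeprefix("ssp"))
        rcp = rcp_part.removeprefix("rcp")
        if ssp not in SSP_IDS or rcp not in RCP_LABELS:
            raise ValueError
    except ValueError:
        raise ValueError(f"cannot parse scenario {text!r}; expected e.g. 'ssp2-rcp4.5'") from None
    return ssp, rcp


def output_name(ssp: int, rcp: str, year: int) -> str:
    """Output raster file name for one scenario-year, e.g. ``ssp2_rcp45_2050.tif``."""
    return f"ssp{ssp}_rcp{rcp.replace('.', '')}_{year}.tif"


def write_raster(grid: FineGrid | CoarseGrid, path, nodata: float = NODATA) -> None:
    """Write a grid as a single-band float32 WGS84 GeoTIFF with nodata sentinel."""
    geom = grid.geometry
    if isinstance(grid, CoarseGrid):
        cell = geom.coarse_cell_size
    else:
        cell = geom.fine_cell_size
    values = grid.values[grid.valid_mask]
    if values.size and not np.all(np.isfinite(values)):
        raise ValueError("grid has non-finite values on valid pixels")
    data = np.where(grid.valid_mask, grid.values, nodata).astype(np.float32)
    tifffile.imwrite(
        path,
        data,
        extratags=[
            (_MODEL_PIXEL_SCALE, "d", 3, (cell, cell, 0.0), True),
            (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, geom.origin_lon, geom.origin_lat, 0.0), True),
            (_GEO_KEY_DIRECTORY, "H", len(_WGS84_GEOKEYS), _WGS84_GEOKEYS, True),
            (_GDAL_NODATA, "s", 0, str(int(nodata)) if nodata == int(nodata) else str(nodata), True),
        ],
    )


def _read_tags(path):
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        if page.samplesperpixel != 1:
            raise ValueError(f"{path}: expected a single-band raster, got {page.samplesperpixel} samples")
        scale_tag = page.tags.get(_MODEL_PIXEL_SCALE)
        tie_tag = page.tags.get(_MODEL_TIEPOINT)
        geo_tag = page.tags.get(_GEO_KEY_DIRECTORY)
        if scale_tag is None or tie_tag is None:
            raise ValueError(f"{path}: missing GeoTIFF referencing tags")
        if geo_tag is not None:
            keys = geo_tag.value
            # GTModelTypeGeoKey (1024) must be 2 = geographic lon/lat
            for i in range(4, len(keys), 4):
                if keys[i] == 1024 and keys[i + 3] != 2:
                    raise ValueError(f"{path}: raster is not in geographic (lon/lat) referencing")
        nodata_tag = page.tags.get(_GDAL_NODATA)
        nodata = float(nodata_tag.value) if nodata_tag is not None else NODATA
        data = page.asarray()
        sx, sy = float(scale_tag.value[0]), float(scale_tag.value[1])
        tie = tie_tag.value
        origin_lon = float(tie[3]) - float(tie[0]) * sx
        origin_lat = float(tie[4]) + float(tie[1]) * sy
    return data, sx, sy, origin_lon, origin_lat, nodata


def read_raster(
    path,
    geometry: GridGeometry | None = None,
    coarse: bool = False,
    refinement: int = 1,
) -> FineGrid | CoarseGrid:
    """Read a GeoTIFF into a grid, resampling to ``geometry`` if needed.

    Parameters
    ----------
    path
        Single-band geographic (lon/lat) GeoTIFF.
    geometry
        Target run geometry.  When given and the file's lattice does not
        already coincide with it, the raster is nearest-neighbor resampled
        onto the target (each target pixel takes the value of the source
        pixel containing its center) with a logged notice.
    coarse
        Interpret the target lattice as the coarse (urban-fraction) one.
    refinement
        Refinement to attach when no target geometry is supplied.
    """
    data, sx, sy, origin_lon, origin_lat, nodata = _read_tags(path)
    data = np.asarray(data, dtype=np.float64)
    nrows, ncols = data.shape

    if geometry is None:
        if abs(sx - sy) > 1e-12:
            raise ValueError(f"{path}: anisotropic pixels ({sx} x {sy}) unsupported")
        if coarse:
            geom = GridGeometry(origin_lon, origin_lat, sx / refinement, refinement,
                                nrows * refinement, ncols * refinement)
        else:
            geom = GridGeometry(origin_lon, origin_lat, sx, refinement,
                                nrows, ncols)
    else:
        geom = geometry

    target_cell = geom.coarse_cell_size if coarse else geom.fine_cell_size
    target_shape = geom.coarse_shape if coarse else geom.fine_shape

    aligned = (
        data.shape == target_shape
        and abs(sx - target_cell) < 1e-12
        and abs(sy - target_cell) < 1e-12
        and abs(origin_lon - geom.origin_lon) < 1e-9
        and abs(origin_lat - geom.origin_lat) < 1e-9
    )
    if not aligned:
        if geometry is None:
            raise ValueError(f"{path}: shape {data.shape} does not match inferred geometry")
        logger.info("%s: resampling (nearest neighbor) onto the run geometry", path)
        data = _resample_nearest(data, sx, sy, origin_lon, origin_lat, geom, target_cell, target_shape)

    mask = (data != nodata) & np.isfinite(data)
    values = np.where(mask, data, 0.0)
    if coarse:
        return CoarseGrid(geom, values, mask)
    return FineGrid(geom, values, mask)


def _resample_nearest(data, sx, sy, olon, olat, geom, target_cell, target_shape):
    """Each target pixel takes the source pixel containing its center."""
    nrows, ncols = target_shape
    lon = geom.origin_lon + (np.arange(ncols) + 0.5) * target_cell
    lat = geom.origin_lat - (np.arange(nrows) + 0.5) * target_cell
    src_col = np.floor((lon - olon) / sx).astype(int)
    src_row = np.floor((olat - lat) / sy).astype(int)
    if (src_col.min() < 0 or src_col.max() >= data.shape[1]
            or src_row.min() < 0 or src_row.max() >= data.shape[0]):
        raise ValueError("target geometry extends beyond the source raster extent")
    return data[np.ix_(src_row, src_col)]


def rasterize_countries(features, geometry: GridGeometry) -> CountryRaster:
    """Burn (id, polygon) features onto the fine lattice by pixel-center test.

    Each fine pixel gets the id of the polygon containing its center;
    uncovered pixels are invalid (water / outside the domain).  Where
    polygons overlap, the later feature wins with a logged warning; a
    polygon covering no pixel centers is also warned about.
    """
    features = list(features)
    if not features:
        raise ValueError("no border features supplied")
    ids_seen = [fid for fid, _ in features]
    if len(set(ids_seen)) != len(ids_seen):
        raise ValueError("country ids must be unique per feature")
    lon, lat = pixel_center_arrays(geometry)
    flat_lon, flat_lat = lon.ravel(), lat.ravel()
    ids = np.zeros(geometry.fine_shape, dtype=np.int32).ravel()
    covered = np.zeros(flat_lon.size, dtype=bool)
    for fid, poly in features:
        geom_obj = poly if isinstance(poly, shapely.Geometry) else shapely_shape(poly)
        inside = shapely.contains_xy(geom_obj, flat_lon, flat_lat)
        if not inside.any():
            logger.warning("country %s: polygon covers no pixel centers", fid)
            continue
        overlap = inside & covered
        if overlap.any():
            logger.warning(
                "country %s overlaps %d already-assigned pixels; later feature wins", fid, int(overlap.sum())
            )
        ids[inside] = int(fid)
        covered |= inside
    return CountryRaster(geometry, ids.reshape(geometry.fine_shape),
                         covered.reshape(geometry.fine_shape))


def read_scenario_csv(path) -> ScenarioSeries:
    """Load a country scenario series (country_id, year, total_population, urban_share)."""
    table = pd.read_csv(path)
    try:
        return ScenarioSeries(table)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def read_matrix_csv(path) -> ScenarioMatrix:
    """Load the SSP x RCP matrix: rows SSP1-5, columns RCP2.6/4.5/6.0/8.5."""
    table = pd.read_csv(path, index_col=0)
    prob: dict[tuple[int, str], float] = {}
    for row_label, row in table.iterrows():
        ssp = int(str(row_label).lower().removeprefix("ssp").strip())
        for col_label, value in row.items():
            rcp = str(col_label).lower().removeprefix("rcp").strip()
            rcp = {"2.6": "2.6", "4.5": "4.5", "6": "6.0", "6.0": "6.0", "8.5": "8.5"}[rcp]
            prob[(ssp, rcp)] = float(value)
    return ScenarioMatrix(prob)


def write_matrix_csv(matrix: ScenarioMatrix, path) -> None:
    table = pd.DataFrame(
        {f"RCP{r}": [matrix.probability[(s, r)] for s in SSP_IDS] for r in RCP_LABELS},
        index=[f"SSP{s}" for s in SSP_IDS],
    )
    table.to_csv(path)


def write_scenario_csv(series: ScenarioSeries, path) -> None:
    series.table.to_csv(path, index=False)


def read_roads_geojson(path) -> list[shapely.LineString]:
    """Road polylines from a GeoJSON FeatureCollection of LineStrings."""
    with open(path) as fh:
        doc = json.load(fh)
    lines = []
    for feature in doc.get("features", []):
        geom_obj = shapely_shape(feature["geometry"])
        if isinstance(geom_obj, shapely.MultiLineString):
            lines.extend(geom_obj.geoms)
        elif isinstance(geom_obj, shapely.LineString):
            lines.append(geom_obj)
        else:
            raise ValueError(f"{path}: unexpected road geometry {geom_obj.geom_type}")
    if not lines:
        raise ValueError(f"{path}: no road polylines found")
    return lines


def write_roads_geojson(roads, path) -> None:
    features = [
        {"type": "Feature", "properties": {}, "geometry": shapely_mapping(r)}
        for r in roads
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_borders_geojson(path) -> list[tuple[int, shapely.Geometry]]:
    """Country border polygons as (country_id, polygon) pairs."""
    with open(path) as fh:
        doc = json.load(fh)
    features = []
    for feature in doc.get("features", []):
        fid = int(feature["properties"]["country_id"])
        features.append((fid, shapely_shape(feature["geometry"])))
    if not features:
        raise ValueError(f"{path}: no border polygons found")
    return features


def write_borders_geojson(features, path) -> None:
    doc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"country_id": int(fid)},
                "geometry": shapely_mapping(poly),
            }
            for fid, poly in features
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)
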