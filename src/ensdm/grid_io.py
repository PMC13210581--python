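"""Grid data model, raster/table I/O and cell geometry.

All stages share one regular north-up lon/lat grid. Rasters are stored as
single-band GeoTIFFs (ModelPixelScale/ModelTiepoint/GeoKeyDirectory tags for
geographic WGS84, GDAL_NODATA for the fill value); occurrence tables travel
as headered CSV.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile

#: authalic Earth radius in km (sphere with the WGS84 ellipsoid's area)
AUTHALIC_RADIUS_KM = 6371.0072

# TIFF tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_TRANSFORM = 34264
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113

# GeoKeyDirectory for plain geographic WGS84, pixel-is-area
_WGS84_GEOKEYS = (
    1, 1, 0, 3,        # version, revision, minor, number of keys
    1024, 0, 1, 2,     # GTModelTypeGeoKey = geographic
    1025, 0, 1, 1,     # GTRasterTypeGeoKey = RasterPixelIsArea
    2048, 0, 1, 4326,  # GeographicTypeGeoKey = WGS84
)


class GridError(ValueError):
    """Raised for malformed or mismatched grids."""


@dataclass(frozen=True)
class GridSpec:
    """Regular square-cell geographic grid, origin at the top-left cell edge."""

    n_rows: int
    n_cols: int
    lon_min: float
    lat_max: float
    cell_size: float
    crs_id: str = "EPSG:4326"

    def __post_init__(self):
        if self.cell_size <= 0:
            raise GridError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise GridError("grid must have at least one row and column")
        if self.lat_max - self.n_rows * self.cell_size < -90 - 1e-9:
            raise GridError("grid extends south of -90 degrees")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lon_center(self, col) -> np.ndarray:
        return self.lon_min + (np.asarray(col) + 0.5) * self.cell_size

    def lat_center(self, row) -> np.ndarray:
        return self.lat_max - (np.asarray(row) + 0.5) * self.cell_size

    def cell_of(self, lon, lat):
        """Containing cell (row, col, inside) under half-open intervals.

        Points on the max-lon / min-lat outer edges fall outside; points on
        interior shared edges belong to the east/south neighbour.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.lon_min) / self.cell_size).astype(int)
        row = np.floor((self.lat_max - lat) / self.cell_size).astype(int)
        # the top edge (lat == lat_max) belongs to row 0
        row = np.where(np.asarray(lat) == self.lat_max, 0, row)
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        return row, col, inside

    def compatible(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and abs(self.lon_min - other.lon_min) <= tol
            and abs(self.lat_max - other.lat_max) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )


@dataclass
class RasterLayer:
    """One predictor or suitability surface with a nodata mask."""

    spec: GridSpec
    values: np.ndarray
    nodata_mask: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.shape != self.spec.shape or self.nodata_mask.shape != self.spec.shape:
            raise GridError(
                f"layer {self.name!r}: array shape {self.values.shape} does not "
                f"match grid {self.spec.shape}"
            )
        if not np.all(np.isfinite(self.values[~self.nodata_mask])):
            raise GridError(f"layer {self.name!r}: non-finite values outside nodata mask")

    def valid_values(self) -> np.ndarray:
        return self.values[~self.nodata_mask]

    def copy_with(self, values=None, name=None) -> "RasterLayer":
        return RasterLayer(
            self.spec,
            self.values.copy() if values is None else values,
            self.nodata_mask.copy(),
            self.name if name is None else name,
        )


class PredictorStack:
    """Ordered collection of co-registered layers for one scenario."""

    def __init__(self, layers: list[RasterLayer], scenario_id: str = "current"):
        if not layers:
            raise GridError("empty stack")
        spec = layers[0].spec
        for lay in layers[1:]:
            if not spec.compatible(lay.spec):
                raise GridError(f"grid mismatch: layer {lay.name!r} is on a different grid")
        names = [lay.name for lay in layers]
        if len(set(names)) != len(names):
            raise GridError(f"duplicate layer names in stack: {names}")
        self.layers = list(layers)
        self.scenario_id = scenario_id

    @property
    def spec(self) -> GridSpec:
        return self.layers[0].spec

    @property
    def names(self) -> list[str]:
        return [lay.name for lay in self.layers]

    def get(self, name: str) -> RasterLayer:
        for lay in self.layers:
            if lay.name == name:
                return lay
        raise KeyError(f"layer {name!r} not in stack {self.scenario_id!r}")

    def union_mask(self) -> np.ndarray:
        mask = np.zeros(self.spec.shape, dtype=bool)
        for lay in self.layers:
            mask |= lay.nodata_mask
        return mask

    def subset(self, names: list[str]) -> "PredictorStack":
        return PredictorStack([self.get(n) for n in names], self.scenario_id)

    def design_at(self, rows, cols, names: list[str] | None = None) -> np.ndarray:
        """Per-cell predictor matrix (len(rows) x n_layers)."""
        names = names or self.names
        return np.column_stack([self.get(n).values[rows, cols] for n in names])


# ---------------------------------------------------------------------------
# raster I/O


def write_raster(layer: RasterLayer, path: str | os.PathLike, nodata=None) -> None:
    """Write a single-band north-up GeoTIFF with the nodata tag set."""
    values = layer.values
    if nodata is None:
        if np.issubdtype(values.dtype, np.integer):
            nodata = -1 if np.min(values, initial=0) >= -1 else np.iinfo(values.dtype).min
        else:
            nodata = -9999.0
    out = values.copy()
    out[layer.nodata_mask] = nodata
    spec = layer.spec
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (spec.cell_size, spec.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, spec.lon_min, spec.lat_max, 0.0)),
        (_TAG_GEO_KEYS, "H", len(_WGS84_GEOKEYS), _WGS84_GEOKEYS),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]
    tifffile.imwrite(
        path, out, photometric="minisblack", extratags=extratags,
        description=layer.name, metadata=None,
    )


def read_raster(path: str | os.PathLike, name: str | None = None) -> RasterLayer:
    """Read a single-band georeferenced raster; nodata becomes the mask."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        tags = page.tags
        if _TAG_TRANSFORM in tags:
            raise GridError(f"{path}: rotated grids (ModelTransformation) are not supported")
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise GridError(f"{path}: missing georeferencing tags")
        sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
        if abs(sx - sy) > 1e-12 * max(sx, sy):
            raise GridError(f"{path}: non-square cells ({sx} x {sy}) are not supported")
        tie = tags[_TAG_TIEPOINT].value
        if tie[0] != 0 or tie[1] != 0:
            raise GridError(f"{path}: tiepoint must anchor the top-left corner")
        lon_min, lat_max = tie[3], tie[4]
        values = page.asarray()
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            txt = tags[_TAG_GDAL_NODATA].value
            nodata = float(txt) if not np.issubdtype(values.dtype, np.integer) else int(float(txt))
        desc = (page.description or "").strip()
    mask = ~np.isfinite(values) if np.issubdtype(values.dtype, np.floating) else np.zeros(values.shape, bool)
    if nodata is not None:
        mask |= values == nodata
    clean = values.copy()
    if np.issubdtype(clean.dtype, np.floating):
        clean[mask] = 0
    spec = GridSpec(values.shape[0], values.shape[1], float(lon_min), float(lat_max), float(sx))
    if name is None:
        name = desc or os.path.splitext(os.path.basename(path))[0]
    return RasterLayer(spec, clean, mask, name)


# ---------------------------------------------------------------------------
# cell geometry


def cell_areas(spec: GridSpec) -> RasterLayer:
    """Exact per-cell spherical area in km², constant along each row.

    A = R² · Δλ · (sin φ_top − sin φ_bot) on the authalic sphere.
    """
    rows = np.arange(spec.n_rows)
    lat_top = np.deg2rad(spec.lat_max - rows * spec.cell_size)
    lat_bot = np.deg2rad(spec.lat_max - (rows + 1) * spec.cell_size)
    dlam = np.deg2rad(spec.cell_size)
    band = AUTHALIC_RADIUS_KM ** 2 * dlam * (np.sin(lat_top) - np.sin(lat_bot))
    values = np.repeat(band[:, None], spec.n_cols, axis=1)
    return RasterLayer(spec, values, np.zeros(spec.shape, bool), name="cell_area_km2")


def extract_values(stack: PredictorStack, points) -> pd.DataFrame:
    """Containing-cell lookup for (lon, lat) points; invalid points flagged.

    Returns a frame with lon, lat, row, col, one column per layer and a
    ``valid`` flag (False outside the grid or on masked cells).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    lon, lat = pts[:, 0], pts[:, 1]
    row, col, inside = stack.spec.cell_of(lon, lat)
    mask = stack.union_mask()
    r = np.where(inside, row, 0)
    c = np.where(inside, col, 0)
    valid = inside & ~mask[r, c]
    out = {"lon": lon, "lat": lat, "row": np.where(inside, row, -1), "col": np.where(inside, col, -1)}
    for lay in stack.layers:
        vals = lay.values[r, c].astype(float)
        vals[~valid] = np.nan
        out[lay.name] = vals
    out["valid"] = valid
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# occurrence table I/O

_OPTIONAL_NUMERIC = ["lon", "lat", "precision_deg", "year", "elevation_m"]
_FLAG_COLS = ["sea_flag", "centroid_flag", "institution_flag"]


def read_occurrences(path: str | os.PathLike):
    """Read an occurrence CSV into an :class:`ensdm.occprep.OccurrenceTable`.

    Requires at least id/lon/lat columns; missing optional fields stay absent
    (NaN) rather than being imputed. Duplicate ids and unparseable
    coordinates are hard errors that name the offending rows.
    """
    from .occprep import OccurrenceTable  # late import to avoid a cycle

    df = pd.read_csv(path, dtype={"id": str})
    missing = {"id", "lon", "lat"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    dup = df["id"][df["id"].duplicated()].unique()
    if len(dup):
        raise ValueError(f"{path}: duplicate ids {list(dup)}")
    for colname in _OPTIONAL_NUMERIC:
        if colname in df.columns:
            coerced = pd.to_numeric(df[colname], errors="coerce")
            bad = coerced.isna() & df[colname].notna() & (df[colname].astype(str).str.strip() != "")
            if bad.any():
                rows = (df.index[bad] + 2).tolist()  # 1-based incl. header
                raise ValueError(f"{path}: unparseable {colname} at rows {rows}")
            df[colname] = coerced
    for colname in _FLAG_COLS:
        if colname not in df.columns:
            df[colname] = False
        else:
            df[colname] = df[colname].fillna(False).astype(bool)
    if "status" not in df.columns:
        df["status"] = "raw"
    if "drop_reason" not in df.columns:
        df["drop_reason"] = pd.NA
    return OccurrenceTable(df)


def write_occurrences(table, path: str | os.PathLike) -> None:
    table.df.to_csv(path, index=False)
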