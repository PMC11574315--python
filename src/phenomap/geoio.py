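"""Raster, tiling and point-table I/O.

Label maps travel as single-band integer GeoTIFFs on the 30 m analysis
grid (ETRS89-extended / LAEA Europe, EPSG:3035 by default), georeferenced
with the standard GeoTIFF tags. Point tables (training/validation
samples) travel as CSV or as GeoPackage point layers. Coordinate
reference systems are carried as metadata only; a table in a different
CRS than the pipeline raises rather than being silently reprojected.

Conventions: nodata code is 0 for label rasters; pixel (row i, col j) of
a raster anchored at upper-left (x0, y0) has its center at
(x0 + (j + 0.5) * px, y0 - (i + 0.5) * px).
"""

from __future__ import annotations

import sqlite3
import struct
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .legend import DEFAULT_LEGEND, NODATA, Legend

DEFAULT_CRS = "EPSG:3035"

# GeoTIFF tag ids
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEOKEYS = 34735
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class GeoTransform:
    """Upper-left anchored north-up affine transform (square pixels)."""

    x0: float
    y0: float
    pixel_size: float

    def pixel_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.x0 + (col + 0.5) * self.pixel_size,
            self.y0 - (row + 0.5) * self.pixel_size,
        )

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        col = int(np.floor((x - self.x0) / self.pixel_size))
        row = int(np.floor((self.y0 - y) / self.pixel_size))
        return row, col


@dataclass
class LabelRaster:
    """One year of class codes on a georeferenced grid."""

    values: np.ndarray  # 2-D integer array
    transform: GeoTransform
    crs: str = DEFAULT_CRS
    nodata: int = NODATA

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _epsg_number(crs: str) -> int:
    if not crs.upper().startswith("EPSG:"):
        raise ValueError(f"only EPSG CRS codes are supported, got {crs!r}")
    return int(crs.split(":")[1])


def _geotags(transform: GeoTransform, crs: str, nodata: int) -> list[tuple]:
    epsg = _epsg_number(crs)
    # minimal GeoKey directory: model=projected, raster=PixelIsArea, PCS=epsg
    geokeys = (
        1, 1, 0, 3,
        1024, 0, 1, 1,
        1025, 0, 1, 1,
        3072, 0, 1, epsg,
    )
    return [
        (_TAG_PIXEL_SCALE, "d", 3, (transform.pixel_size, transform.pixel_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, transform.x0, transform.y0, 0.0)),
        (_TAG_GEOKEYS, "H", len(geokeys), geokeys),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]


def write_label_raster(
    raster: LabelRaster, path: str | Path, legend: Legend = DEFAULT_LEGEND
) -> Path:
    """Write a single-band byte GeoTIFF with georeference and nodata tags."""
    path = Path(path)
    values = np.asarray(raster.values)
    if not np.issubdtype(values.dtype, np.integer):
        raise ValueError("label raster must hold integer codes")
    bad = legend.validate_codes(values)
    if bad:
        raise ValueError(f"codes outside legend: {bad}")
    tifffile.imwrite(
        path,
        values.astype(np.uint8),
        extratags=_geotags(raster.transform, raster.crs, raster.nodata),
    )
    return path


def _parse_geo(page) -> tuple[GeoTransform, str, int | None]:
    tags = page.tags
    if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
        raise ValueError("raster has no georeference (missing GeoTIFF tags)")
    sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
    if abs(sx - sy) > 1e-9:
        raise ValueError("non-square pixels are not supported")
    tie = tags[_TAG_TIEPOINT].value
    x0 = tie[3] - tie[0] * sx
    y0 = tie[4] + tie[1] * sy
    crs = DEFAULT_CRS
    if _TAG_GEOKEYS in tags:
        keys = tags[_TAG_GEOKEYS].value
        for k in range(4, len(keys), 4):
            if keys[k] == 3072:
                crs = f"EPSG:{keys[k + 3]}"
    else:
        raise ValueError("raster has no CRS (missing GeoKey directory)")
    nodata = None
    if _TAG_GDAL_NODATA in tags:
        nodata = int(float(tags[_TAG_GDAL_NODATA].value))
    return GeoTransform(float(x0), float(y0), float(sx)), crs, nodata


def read_label_raster(path: str | Path, legend: Legend = DEFAULT_LEGEND) -> LabelRaster:
    """Read a single-band integer GeoTIFF; flags codes outside the legend."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        transform, crs, nodata = _parse_geo(page)
    if values.ndim != 2:
        raise ValueError("label raster must be single-band")
    if not np.issubdtype(values.dtype, np.integer):
        raise ValueError("label raster must hold an integer band")
    bad = legend.validate_codes(values)
    if bad:
        raise ValueError(f"codes outside legend: {bad}")
    return LabelRaster(values, transform, crs, NODATA if nodata is None else nodata)


def write_band_stack(values: np.ndarray, transform: GeoTransform, path: str | Path,
                     crs: str = DEFAULT_CRS) -> Path:
    """Write a (bands, rows, cols) float32 stack as a multi-page GeoTIFF."""
    path = Path(path)
    arr = np.asarray(values, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None]
    tifffile.imwrite(path, arr, extratags=_geotags(transform, crs, 0))
    return path


def read_band_stack(path: str | Path) -> tuple[np.ndarray, GeoTransform, str]:
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        transform, crs, _ = _parse_geo(tif.pages[0])
    if arr.ndim == 2:
        arr = arr[None]
    return arr, transform, crs


# ---------------------------------------------------------------------------
# tiling

@dataclass(frozen=True)
class TileGrid:
    """Regular square tiling of the projected plane, default 30x30 km / 30 m."""

    origin: tuple[float, float] = (0.0, 0.0)
    tile_size: float = 30_000.0
    pixel_size: float = 30.0
    crs: str = DEFAULT_CRS

    def __post_init__(self) -> None:
        ratio = self.tile_size / self.pixel_size
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("tile_size must be an integer multiple of pixel_size")

    @property
    def pixels_per_tile(self) -> int:
        return int(round(self.tile_size / self.pixel_size))


def tile_extent(
    grid: TileGrid, extent: tuple[float, float, float, float]
) -> list[tuple[float, float, float, float]]:
    """Tiles (xmin, ymin, xmax, ymax) covering `extent`, aligned to the origin.

    Tiles are half-open on their max edges so the returned set is a
    partition: pairwise disjoint with union covering the request.
    """
    xmin, ymin, xmax, ymax = extent
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("extent must be non-empty")
    ox, oy = grid.origin
    t = grid.tile_size
    i0 = int(np.floor((xmin - ox) / t))
    i1 = int(np.ceil((xmax - ox) / t))
    j0 = int(np.floor((ymin - oy) / t))
    j1 = int(np.ceil((ymax - oy) / t))
    tiles = []
    for j in range(j0, j1):
        for i in range(i0, i1):
            tiles.append((ox + i * t, oy + j * t, ox + (i + 1) * t, oy + (j + 1) * t))
    return tiles


# ---------------------------------------------------------------------------
# point tables

POINT_COLUMNS = ["x", "y", "year", "class_code"]
YEAR_RANGE = (2000, 2022)


def _check_years(df: pd.DataFrame) -> None:
    out = df[(df["year"] < YEAR_RANGE[0]) | (df["year"] > YEAR_RANGE[1])]
    if len(out):
        warnings.warn(
            f"{len(out)} points have years outside {YEAR_RANGE[0]}-{YEAR_RANGE[1]}; kept",
            stacklevel=3,
        )


def read_points(path: str | Path, crs: str = DEFAULT_CRS) -> pd.DataFrame:
    """Read a labeled point table (CSV or GeoPackage) with columns x, y, year, class_code."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".gpkg":
        df, file_crs = _read_gpkg_points(path)
    else:
        df = pd.read_csv(path)
        file_crs = crs
    missing = [c for c in POINT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"point table missing required columns: {missing}")
    if file_crs != crs:
        raise ValueError(
            f"point table CRS {file_crs} differs from pipeline CRS {crs}; "
            "reproject upstream (no reprojection engine is provided)"
        )
    df = df[POINT_COLUMNS].astype({"year": int, "class_code": int})
    _check_years(df)
    return df.reset_index(drop=True)


def write_points_csv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df[POINT_COLUMNS].to_csv(path, index=False)
    return path


# GeoPackage point layers via sqlite3: standard GPKG binary header + WKB point.

def _read_gpkg_points(path: Path) -> tuple[pd.DataFrame, str]:
    con = sqlite3.connect(path)
    try:
        row = con.execute(
            "SELECT c.table_name, c.srs_id FROM gpkg_contents c WHERE c.data_type='features'"
        ).fetchone()
        if row is None:
            raise ValueError("GeoPackage has no feature layer")
        table, srs_id = row
        rows = con.execute(
            f'SELECT geom, year, class_code FROM "{table}"'
        ).fetchall()
    finally:
        con.close()
    xs, ys, years, codes = [], [], [], []
    for geom, year, code in rows:
        x, y = _parse_gpkg_point(geom)
        xs.append(x)
        ys.append(y)
        years.append(year)
        codes.append(code)
    df = pd.DataFrame({"x": xs, "y": ys, "year": years, "class_code": codes})
    return df, f"EPSG:{srs_id}"


def _parse_gpkg_point(blob: bytes) -> tuple[float, float]:
    if blob[:2] != b"GP":
        raise ValueError("not a GeoPackage geometry blob")
    flags = blob[3]
    env_len = {0: 0, 1: 32, 2: 48, 3: 48, 4: 64}[(flags >> 1) & 0b111]
    wkb = blob[8 + env_len:]
    byte_order = "<" if wkb[0] == 1 else ">"
    (geom_type,) = struct.unpack(byte_order + "I", wkb[1:5])
    if geom_type % 1000 != 1:
        raise ValueError("only point geometries are supported")
    x, y = struct.unpack(byte_order + "dd", wkb[5:21])
    return x, y


def write_points_gpkg(df: pd.DataFrame, path: str | Path, crs: str = DEFAULT_CRS,
                      layer: str = "points") -> Path:
    """Write a minimal standards-conforming GeoPackage point layer."""
    path = Path(path)
    if path.exists():
        path.unlink()
    srs_id = _epsg_number(crs)
    con = sqlite3.connect(path)
    try:
        con.execute("PRAGMA application_id = 0x47504B47")  # 'GPKG'
        con.execute("PRAGMA user_version = 10300")
        con.execute(
            "CREATE TABLE gpkg_spatial_ref_sys (srs_name TEXT NOT NULL, srs_id INTEGER "
            "PRIMARY KEY, organization TEXT NOT NULL, organization_coordsys_id INTEGER "
            "NOT NULL, definition TEXT NOT NULL, description TEXT)"
        )
        con.execute(
            "INSERT INTO gpkg_spatial_ref_sys VALUES (?, ?, 'EPSG', ?, 'undefined', NULL)",
            (crs, srs_id, srs_id),
        )
        con.execute(
            "CREATE TABLE gpkg_contents (table_name TEXT PRIMARY KEY, data_type TEXT NOT "
            "NULL, identifier TEXT, description TEXT, last_change TEXT, min_x DOUBLE, "
            "min_y DOUBLE, max_x DOUBLE, max_y DOUBLE, srs_id INTEGER)"
        )
        con.execute(
            "CREATE TABLE gpkg_geometry_columns (table_name TEXT NOT NULL, column_name "
            "TEXT NOT NULL, geometry_type_name TEXT NOT NULL, srs_id INTEGER NOT NULL, "
            "z TINYINT NOT NULL, m TINYINT NOT NULL)"
        )
        con.execute(
            f'CREATE TABLE "{layer}" (fid INTEGER PRIMARY KEY AUTOINCREMENT, geom BLOB, '
            "year INTEGER, class_code INTEGER)"
        )
        con.execute(
            "INSERT INTO gpkg_contents (table_name, data_type, identifier, srs_id) "
            "VALUES (?, 'features', ?, ?)",
            (layer, layer, srs_id),
        )
        con.execute(
            "INSERT INTO gpkg_geometry_columns VALUES (?, 'geom', 'POINT', ?, 0, 0)",
            (layer, srs_id),
        )
        for _, r in df.iterrows():
            # version 0, flags 0x01: little-endian header, no envelope
            header = b"GP" + bytes([0, 1]) + struct.pack("<i", srs_id)
            wkb = struct.pack("<BIdd", 1, 1, float(r["x"]), float(r["y"]))
            con.execute(
                f'INSERT INTO "{layer}" (geom, year, class_code) VALUES (?, ?, ?)',
                (header + wkb, int(r["year"]), int(r["class_code"])),
            )
        con.commit()
    finally:
        con.close()
    return path
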