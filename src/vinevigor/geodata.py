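"""Core geospatial containers and I/O.

Rasters are plain 2-D numpy grids with a north-up georeference and a nodata
sentinel; multiband imagery is a :class:`BandStack` keyed by band role in the
MicaSense RedEdge-MX band order (blue, green, red, red_edge, nir).  GeoTIFF
round-tripping is built on :mod:`tifffile`, writing the standard GeoTIFF tags
(ModelPixelScale, ModelTiepoint, GeoKeyDirectory) plus the GDAL nodata tag.

Coordinate convention: pixel centers sit at integer ``(row, col)``; row 0 /
col 0 is the north-west pixel and rows increase southward.  Only north-up
(rotation 0) rasters are supported; oriented geometry is carried by sampling
rectangles, not by rasters.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import tifffile

__all__ = [
    "GridGeoreference",
    "Raster",
    "BandStack",
    "VineRecord",
    "BAND_ORDER",
    "GROWTH_CLASSES",
    "CLASS_COLOR_CODES",
    "world_to_pixel",
    "pixel_to_world",
    "read_raster",
    "write_raster",
    "read_band_stack",
    "write_band_stack",
    "read_vine_points",
    "write_vine_points",
]

#: Band roles in orthomosaic band order (band 1 = blue ... band 5 = nir).
BAND_ORDER: tuple[str, ...] = ("blue", "green", "red", "red_edge", "nir")

#: The six ordinal growth classes, from no growth (0) to excessive growth (9).
GROWTH_CLASSES: tuple[int, ...] = (0, 1, 3, 5, 7, 9)

#: Field color legend for the growth classes.
CLASS_COLOR_CODES: dict[int, str] = {
    0: "dark red",
    1: "red",
    3: "orange",
    5: "cyan",
    7: "green",
    9: "dark green",
}

DEFAULT_NODATA = -9999.0

# GeoTIFF / GDAL tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113

# GeoKey ids
_KEY_GT_MODEL_TYPE = 1024
_KEY_GT_RASTER_TYPE = 1025
_KEY_PROJECTED_CRS = 3072


@dataclass(frozen=True)
class GridGeoreference:
    """North-up affine georeference with pixel centers at integer indices.

    ``origin_easting`` / ``origin_northing`` locate the *center* of pixel
    (0, 0); ``pixel_size`` is the square cell size in meters.
    """

    origin_easting: float
    origin_northing: float
    pixel_size: float
    rotation: float = 0.0
    crs_code: str = "EPSG:25832"

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if not 0.0 <= self.rotation < 360.0:
            raise ValueError(f"rotation must lie in [0, 360), got {self.rotation}")
        if self.rotation != 0.0:
            raise NotImplementedError("only north-up (rotation=0) rasters are supported")


def world_to_pixel(georef: GridGeoreference, easting: float, northing: float) -> tuple[float, float]:
    """Map world coordinates (m) to fractional ``(row, col)``.

    Inverse of :func:`pixel_to_world`.  Out-of-bounds coordinates return
    out-of-range indices; callers clip.
    """
    col = (np.asarray(easting) - georef.origin_easting) / georef.pixel_size
    row = (georef.origin_northing - np.asarray(northing)) / georef.pixel_size
    if np.ndim(col) == 0:
        return float(row), float(col)
    return row, col


def pixel_to_world(georef: GridGeoreference, row: float, col: float) -> tuple[float, float]:
    """Map fractional ``(row, col)`` to world ``(easting, northing)`` in m."""
    easting = georef.origin_easting + np.asarray(col) * georef.pixel_size
    northing = georef.origin_northing - np.asarray(row) * georef.pixel_size
    if np.ndim(easting) == 0:
        return float(easting), float(northing)
    return easting, northing


@dataclass
class Raster:
    """A georeferenced 2-D grid of reals with a nodata sentinel."""

    values: np.ndarray
    georef: GridGeoreference
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError(f"raster values must be 2-D and non-empty, got shape {self.values.shape}")
        bad = ~np.isfinite(self.values) & ~np.isnan(self.values)
        if bad.any():
            raise ValueError("raster cells must be finite or nodata")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def pixel_size(self) -> float:
        return self.georef.pixel_size

    def valid_mask(self) -> np.ndarray:
        """Boolean grid: True where the cell holds data."""
        return (self.values != self.nodata) & np.isfinite(self.values)

    def to_masked(self) -> np.ndarray:
        """Values with nodata replaced by NaN (always a copy)."""
        out = self.values.astype(np.float64, copy=True)
        out[~self.valid_mask()] = np.nan
        return out

    def with_values(self, values: np.ndarray, nodata: float | None = None) -> "Raster":
        """New co-registered raster carrying ``values``."""
        return Raster(values, self.georef, self.nodata if nodata is None else nodata)


def _same_grid(a: Raster, b: Raster) -> bool:
    return a.shape == b.shape and a.georef == b.georef


def require_coregistered(*rasters: Raster, context: str = "operation") -> None:
    first = rasters[0]
    for other in rasters[1:]:
        if not _same_grid(first, other):
            raise ValueError(
                f"{context}: rasters are not co-registered "
                f"(shape/georef {first.shape}/{first.georef} vs {other.shape}/{other.georef})"
            )


@dataclass
class BandStack:
    """Co-registered band-role-keyed reflectance rasters."""

    bands: Mapping[str, Raster]

    def __post_init__(self) -> None:
        unknown = set(self.bands) - set(BAND_ORDER)
        if unknown:
            raise ValueError(f"unknown band roles {sorted(unknown)}; allowed: {BAND_ORDER}")
        rasters = list(self.bands.values())
        if not rasters:
            raise ValueError("band stack needs at least one band")
        require_coregistered(*rasters, context="band stack")

    def __getitem__(self, role: str) -> Raster:
        return self.bands[role]

    def __contains__(self, role: str) -> bool:
        return role in self.bands

    @property
    def georef(self) -> GridGeoreference:
        return next(iter(self.bands.values())).georef

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.bands.values())).shape

    def require(self, roles: Iterable[str], context: str) -> None:
        missing = [r for r in roles if r not in self.bands]
        if missing:
            raise ValueError(f"{context}: band(s) {missing} missing from stack (has {sorted(self.bands)})")


@dataclass(frozen=True)
class VineRecord:
    """A single vine: stem position plus its field-assessed growth class."""

    vine_id: int
    easting: float
    northing: float
    growth_class: int
    color_code: str = ""

    def __post_init__(self) -> None:
        if self.growth_class not in GROWTH_CLASSES:
            raise ValueError(
                f"vine {self.vine_id}: growth_class {self.growth_class} not in {GROWTH_CLASSES}"
            )
        if not self.color_code:
            object.__setattr__(self, "color_code", CLASS_COLOR_CODES[self.growth_class])


# ---------------------------------------------------------------------------
# GeoTIFF I/O
# ---------------------------------------------------------------------------

def _geo_extratags(georef: GridGeoreference, nodata: float) -> list[tuple]:
    ps = float(georef.pixel_size)
    epsg = 0
    if georef.crs_code.upper().startswith("EPSG:"):
        epsg = int(georef.crs_code.split(":", 1)[1])
    # GTRasterTypeGeoKey = 2 (PixelIsPoint): tiepoint refers to the pixel center.
    keys = [
        (1, 1, 0, 3),
        (_KEY_GT_MODEL_TYPE, 0, 1, 1),
        (_KEY_GT_RASTER_TYPE, 0, 1, 2),
        (_KEY_PROJECTED_CRS, 0, 1, epsg),
    ]
    directory = [v for entry in keys for v in entry]
    return [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (ps, ps, 0.0), True),
        (
            _TAG_MODEL_TIEPOINT,
            "d",
            6,
            (0.0, 0.0, 0.0, float(georef.origin_easting), float(georef.origin_northing), 0.0),
            True,
        ),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(directory), tuple(directory), True),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata), True),
    ]


def write_raster(raster: Raster | Sequence[Raster], path: str | Path) -> Path:
    """Write one raster (or a co-registered list, one band per page) as GeoTIFF.

    Payloads are stored as float32.
    """
    path = Path(path)
    rasters = [raster] if isinstance(raster, Raster) else list(raster)
    require_coregistered(*rasters, context=f"write_raster({path})")
    tags = _geo_extratags(rasters[0].georef, rasters[0].nodata)
    with tifffile.TiffWriter(path) as tif:
        for band in rasters:
            tif.write(
                band.values.astype(np.float32),
                photometric="minisblack",
                extratags=tags,
                contiguous=False,
            )
    return path


def _parse_georef(page: "tifffile.TiffPage", path: Path) -> tuple[GridGeoreference, float]:
    tags = page.tags
    if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
        raise ValueError(f"{path}: missing georeference (ModelPixelScale/ModelTiepoint tags)")
    scale = tags[_TAG_MODEL_PIXEL_SCALE].value
    tiepoint = tags[_TAG_MODEL_TIEPOINT].value
    if not math.isclose(scale[0], scale[1], rel_tol=1e-9):
        raise ValueError(f"{path}: non-square pixels are not supported")
    crs = "EPSG:25832"
    pixel_is_area = False
    if _TAG_GEO_KEY_DIRECTORY in tags:
        directory = tags[_TAG_GEO_KEY_DIRECTORY].value
        for i in range(4, len(directory), 4):
            key, _, _, value = directory[i : i + 4]
            if key == _KEY_PROJECTED_CRS and value:
                crs = f"EPSG:{value}"
            if key == _KEY_GT_RASTER_TYPE:
                pixel_is_area = value == 1
    # Tiepoint gives world coords of raster point (0, 0); under PixelIsArea that
    # is the outer corner of the first pixel, shift by half a cell to the center.
    i, j, _, x, y, _ = tiepoint[:6]
    ox = x - j * scale[0]
    oy = y + i * scale[1]
    if pixel_is_area:
        ox += scale[0] / 2.0
        oy -= scale[1] / 2.0
    nodata = DEFAULT_NODATA
    if _TAG_GDAL_NODATA in tags:
        nodata = float(tags[_TAG_GDAL_NODATA].value)
    return GridGeoreference(ox, oy, float(scale[0]), 0.0, crs), nodata


def read_raster(path: str | Path) -> Raster | list[Raster]:
    """Read a GeoTIFF; multiband/multipage files return a list of rasters."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with tifffile.TiffFile(path) as tif:
            georef, nodata = _parse_georef(tif.pages[0], path)
            arrays: list[np.ndarray] = []
            for page in tif.pages:
                data = page.asarray()
                if data.ndim == 3:  # pixel-interleaved multiband page
                    arrays.extend(data[..., k] for k in range(data.shape[-1]))
                else:
                    arrays.append(data)
    except tifffile.TiffFileError as exc:
        raise ValueError(f"{path}: unreadable TIFF ({exc})") from exc
    rasters = [Raster(a.astype(np.float64), georef, nodata) for a in arrays]
    return rasters[0] if len(rasters) == 1 else rasters


def write_band_stack(stack: BandStack, path: str | Path) -> Path:
    """Write a 5-band stack in orthomosaic band order (blue=1 ... nir=5)."""
    roles = [r for r in BAND_ORDER if r in stack]
    return write_raster([stack[r] for r in roles], path)


def read_band_stack(path: str | Path, roles: Sequence[str] = BAND_ORDER) -> BandStack:
    """Read a multiband GeoTIFF, assigning roles in orthomosaic band order."""
    rasters = read_raster(path)
    if isinstance(rasters, Raster):
        rasters = [rasters]
    if len(rasters) != len(roles):
        raise ValueError(f"{path}: expected {len(roles)} bands ({roles}), found {len(rasters)}")
    return BandStack(dict(zip(roles, rasters)))


# ---------------------------------------------------------------------------
# Vine point I/O (CSV and GeoJSON)
# ---------------------------------------------------------------------------

_CSV_HEADER = ["vine_id", "easting", "northing", "growth_class"]


def _validate_records(records: list[VineRecord]) -> list[VineRecord]:
    ids = [r.vine_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate vine_id values: {dupes}")
    return records


def read_vine_points(path: str | Path) -> list[VineRecord]:
    """Read vine stem points from CSV or GeoJSON; validates classes and ids."""
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("{"):
        return _read_vine_geojson(text, path)
    return _read_vine_csv(text, path)


def _read_vine_csv(text: str, path: Path) -> list[VineRecord]:
    reader = csv.DictReader(text.splitlines())
    missing = set(_CSV_HEADER) - set(reader.fieldnames or [])
    if missing:
        raise ValueError(f"{path}: missing CSV columns {sorted(missing)}")
    records, bad = [], []
    for row in reader:
        vid = int(row["vine_id"])
        gc = int(row["growth_class"])
        if gc not in GROWTH_CLASSES:
            bad.append((vid, gc))
            continue
        records.append(
            VineRecord(vid, float(row["easting"]), float(row["northing"]), gc, row.get("color_code", ""))
        )
    if bad:
        raise ValueError(f"{path}: growth_class outside {GROWTH_CLASSES} for vine rows {bad}")
    return _validate_records(records)


def _read_vine_geojson(text: str, path: Path) -> list[VineRecord]:
    obj = json.loads(text)
    records, bad = [], []
    for feature in obj.get("features", []):
        props = feature.get("properties", {})
        x, y = feature["geometry"]["coordinates"][:2]
        vid = int(props["vine_id"])
        gc = int(props["growth_class"])
        if gc not in GROWTH_CLASSES:
            bad.append((vid, gc))
            continue
        records.append(VineRecord(vid, float(x), float(y), gc, props.get("color_code", "")))
    if bad:
        raise ValueError(f"{path}: growth_class outside {GROWTH_CLASSES} for vines {bad}")
    return _validate_records(records)


def write_vine_points(records: Sequence[VineRecord], path: str | Path, crs_code: str = "EPSG:25832") -> Path:
    """Write vine points as CSV (``.csv``) or GeoJSON (anything else)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_CSV_HEADER + ["color_code"])
            for r in records:
                writer.writerow([r.vine_id, repr(r.easting), repr(r.northing), r.growth_class, r.color_code])
    else:
        features = [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [r.easting, r.northing]},
                "properties": {
                    "vine_id": r.vine_id,
                    "growth_class": r.growth_class,
                    "color_code": r.color_code,
                },
            }
            for r in records
        ]
        obj = {
            "type": "FeatureCollection",
            "crs": {"type": "name", "properties": {"name": crs_code}},
            "features": features,
        }
        path.write_text(json.dumps(obj, indent=1))
    return path
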