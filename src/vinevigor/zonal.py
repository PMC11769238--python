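"""Per-vine oriented sampling rectangles and masked zonal statistics.

Each vine gets a 1.0 m (across row) x 1.2 m (along row) rectangle centered
on its stem, with the along-row axis oriented parallel to the mean terrain
aspect (rows run in the fall line).  Pixels belong to a rectangle when their
center falls inside it (half-open test in the rectangle frame, so a pixel on
the lower edge of an axis-aligned rectangle belongs, one on the upper edge
does not).  Statistics use the population variance convention.

The assembled feature table carries the 17 per-vine features (six
vegetation-index means, seven CHM statistics incl. volume, four red-band
texture means) plus the growth-class label, and the seven progressive
feature-group selections used for model training.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .canopy import chm_volume
from .geodata import GridGeoreference, Raster, VineRecord, require_coregistered

__all__ = [
    "SamplingRectangle",
    "ZonalStats",
    "FEATURE_COLUMNS",
    "FEATURE_GROUPS",
    "build_rectangle",
    "rectangle_pixels",
    "zonal_statistics",
    "mean_terrain_aspect",
    "assemble_feature_table",
    "select_feature_group",
]

logger = logging.getLogger(__name__)

#: Modeled feature columns.
VI_COLUMNS = ("NDVI", "NDVIRE", "OSAVI", "GNDVI", "NDWI", "TSAVI")
CHM_COLUMNS = ("CHM_mean", "CHM_median", "CHM_min", "CHM_max", "CHM_std", "CHM_var", "CHM_Volume")
TEXTURE_COLUMNS = ("Contrast", "Correlation", "Entropy", "ASM")
FEATURE_COLUMNS: tuple[str, ...] = VI_COLUMNS + CHM_COLUMNS + TEXTURE_COLUMNS

#: Map of spectral index name -> feature column name.
VI_COLUMN_OF = {"NDVI": "NDVI", "NDREI": "NDVIRE", "OSAVI": "OSAVI", "GNDVI": "GNDVI", "NDWI": "NDWI", "TSAVI": "TSAVI"}

#: Texture measure -> feature column name.
TEXTURE_COLUMN_OF = {"CON": "Contrast", "COR": "Correlation", "ENT": "Entropy", "ASM": "ASM"}

#: The seven progressive input feature groups (spectral / structural /
#: texture and their combinations); group sizes 6, 4, 4, 10, 10, 8, 14.
_STRUCTURAL_GROUP = ("CHM_mean", "CHM_max", "CHM_std", "CHM_Volume")
FEATURE_GROUPS: dict[int, tuple[str, ...]] = {
    1: VI_COLUMNS,
    2: _STRUCTURAL_GROUP,
    3: TEXTURE_COLUMNS,
    4: VI_COLUMNS + _STRUCTURAL_GROUP,
    5: VI_COLUMNS + TEXTURE_COLUMNS,
    6: _STRUCTURAL_GROUP + TEXTURE_COLUMNS,
    7: VI_COLUMNS + _STRUCTURAL_GROUP + TEXTURE_COLUMNS,
}


@dataclass(frozen=True)
class SamplingRectangle:
    """Oriented per-vine sampling zone; orientation is the azimuth (deg,
    clockwise from north) of the along-row axis."""

    center: tuple[float, float]
    across_row_width: float = 1.0
    along_row_length: float = 1.2
    orientation_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.across_row_width <= 0 or self.along_row_length <= 0:
            raise ValueError("rectangle dimensions must be positive")

    @property
    def area(self) -> float:
        return self.across_row_width * self.along_row_length

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        """Unit vectors (easting, northing) of the along- and across-row axes."""
        az = math.radians(self.orientation_deg)
        along = np.array([math.sin(az), math.cos(az)])
        return along, np.array([-along[1], along[0]])

    def corners(self) -> np.ndarray:
        """(4, 2) corner coordinates, counterclockwise."""
        along, across = self.axes()
        c = np.asarray(self.center)
        hl = self.along_row_length / 2.0
        hw = self.across_row_width / 2.0
        return np.array(
            [c + s1 * hl * along + s2 * hw * across for s1, s2 in ((-1, -1), (1, -1), (1, 1), (-1, 1))]
        )


def build_rectangle(
    vine: VineRecord,
    aspect_deg: float,
    dims: tuple[float, float] = (1.0, 1.2),
) -> SamplingRectangle:
    """Sampling rectangle centered on the vine, along-row axis parallel to
    the terrain aspect (``dims`` = (across-row width, along-row length))."""
    return SamplingRectangle(
        center=(vine.easting, vine.northing),
        across_row_width=dims[0],
        along_row_length=dims[1],
        orientation_deg=aspect_deg % 360.0,
    )


def rectangle_pixels(rect: SamplingRectangle, georef: GridGeoreference, shape: tuple[int, int]) -> np.ndarray:
    """(n, 2) array of (row, col) pixels whose centers fall in the rectangle.

    Half-open membership in the rectangle frame: lower edges inclusive,
    upper edges exclusive, so pixel ownership is unambiguous on boundaries.
    """
    ps = georef.pixel_size
    half_diag = math.hypot(rect.along_row_length, rect.across_row_width) / 2.0
    cx, cy = rect.center
    row_c = (georef.origin_northing - cy) / ps
    col_c = (cx - georef.origin_easting) / ps
    pad = int(math.ceil(half_diag / ps)) + 1
    r_lo = max(0, int(math.floor(row_c)) - pad)
    r_hi = min(shape[0], int(math.ceil(row_c)) + pad + 1)
    c_lo = max(0, int(math.floor(col_c)) - pad)
    c_hi = min(shape[1], int(math.ceil(col_c)) + pad + 1)
    if r_lo >= r_hi or c_lo >= c_hi:
        return np.empty((0, 2), dtype=np.int64)
    rows, cols = np.meshgrid(np.arange(r_lo, r_hi), np.arange(c_lo, c_hi), indexing="ij")
    east = georef.origin_easting + cols * ps
    north = georef.origin_northing - rows * ps
    along, across = rect.axes()
    u = (east - cx) * along[0] + (north - cy) * along[1]
    v = (east - cx) * across[0] + (north - cy) * across[1]
    hl = rect.along_row_length / 2.0
    hw = rect.across_row_width / 2.0
    inside = (u >= -hl) & (u < hl) & (v >= -hw) & (v < hw)
    return np.column_stack([rows[inside], cols[inside]]).astype(np.int64)


@dataclass(frozen=True)
class ZonalStats:
    """Summary statistics of a masked pixel selection (population variance)."""

    mean: float
    std: float
    variance: float
    min: float
    max: float
    range: float
    median: float
    count: int

    @classmethod
    def empty(cls) -> "ZonalStats":
        nan = float("nan")
        return cls(nan, nan, nan, nan, nan, nan, nan, 0)


def zonal_statistics(raster: Raster, pixels: np.ndarray, mask: Raster | None = None) -> ZonalStats:
    """Statistics of raster values over ``pixels`` where the mask is 1.

    Invalid raster cells are skipped; an empty selection yields NaN stats
    with count 0.
    """
    pixels = np.asarray(pixels, dtype=np.int64).reshape(-1, 2)
    if pixels.size == 0:
        return ZonalStats.empty()
    nrows, ncols = raster.shape
    keep = (pixels[:, 0] >= 0) & (pixels[:, 0] < nrows) & (pixels[:, 1] >= 0) & (pixels[:, 1] < ncols)
    pixels = pixels[keep]
    if pixels.size == 0:
        return ZonalStats.empty()
    rows, cols = pixels[:, 0], pixels[:, 1]
    select = raster.valid_mask()[rows, cols]
    if mask is not None:
        require_coregistered(raster, mask, context="zonal_statistics")
        select &= mask.values[rows, cols] == 1
    values = raster.values[rows[select], cols[select]]
    if values.size == 0:
        return ZonalStats.empty()
    return ZonalStats(
        mean=float(values.mean()),
        std=float(values.std()),
        variance=float(values.var()),
        min=float(values.min()),
        max=float(values.max()),
        range=float(values.max() - values.min()),
        median=float(np.median(values)),
        count=int(values.size),
    )


def mean_terrain_aspect(dtm: Raster) -> float:
    """Circular mean azimuth (deg clockwise from north) of steepest descent.

    Finite differences account for rows increasing southward.
    """
    valid = dtm.valid_mask()
    z = np.where(valid, dtm.values, np.nan)
    dz_drow, dz_dcol = np.gradient(z, dtm.pixel_size)
    dz_dx = dz_dcol  # east
    dz_dy = -dz_drow  # north (row index increases southward)
    az = np.arctan2(-dz_dx, -dz_dy)  # azimuth of -gradient
    ok = np.isfinite(az)
    if not ok.any():
        raise ValueError("DTM has no valid gradient cells")
    mean = math.atan2(float(np.sin(az[ok]).mean()), float(np.cos(az[ok]).mean()))
    return math.degrees(mean) % 360.0


def assemble_feature_table(
    vines: Sequence[VineRecord],
    vi_rasters: Mapping[str, Raster],
    chm: Raster,
    texture_rasters: Mapping[str, Raster],
    mask: Raster,
    dtm: Raster,
    rectangle_dims: tuple[float, float] = (1.0, 1.2),
) -> pd.DataFrame:
    """One row per vine: masked-rectangle features joined with the label.

    Vegetation-index and texture features aggregate by the masked-rectangle
    mean; CHM contributes its seven statistics including the volume.  Vines
    with an empty mask intersection keep their CHM_Volume of 0 but have NaN
    spectral/texture features and are flagged ``excluded`` for modeling.
    """
    rasters = list(vi_rasters.values()) + [chm, mask, dtm] + list(texture_rasters.values())
    require_coregistered(*rasters, context="assemble_feature_table")
    aspect = mean_terrain_aspect(dtm)
    georef = chm.georef
    shape = chm.shape

    records = []
    for vine in vines:
        rect = build_rectangle(vine, aspect, rectangle_dims)
        pixels = rectangle_pixels(rect, georef, shape)
        row: dict[str, object] = {"vine_id": vine.vine_id, "growth_class": vine.growth_class}
        for vi_name, raster in vi_rasters.items():
            stats = zonal_statistics(raster, pixels, mask)
            row[VI_COLUMN_OF.get(vi_name, vi_name)] = stats.mean
        chm_stats = zonal_statistics(chm, pixels, mask)
        row.update(
            CHM_mean=chm_stats.mean,
            CHM_median=chm_stats.median,
            CHM_min=chm_stats.min,
            CHM_max=chm_stats.max,
            CHM_std=chm_stats.std,
            CHM_var=chm_stats.variance,
            CHM_Volume=chm_volume(chm, mask, pixels),
        )
        for t_name, raster in texture_rasters.items():
            stats = zonal_statistics(raster, pixels, mask)
            row[TEXTURE_COLUMN_OF.get(t_name, t_name)] = stats.mean
        row["count"] = chm_stats.count
        row["excluded"] = chm_stats.count == 0
        records.append(row)

    table = pd.DataFrame.from_records(records).set_index("vine_id")
    n_excluded = int(table["excluded"].sum())
    if n_excluded:
        logger.info("feature table: %d of %d vines have an empty mask intersection", n_excluded, len(table))
    return table


def select_feature_group(table: pd.DataFrame, group_id: int) -> pd.DataFrame:
    """Restrict the feature table to one of the seven input feature groups
    (growth_class is carried along)."""
    if group_id not in FEATURE_GROUPS:
        raise ValueError(f"unknown feature group {group_id}; valid ids: 1..7")
    columns = list(FEATURE_GROUPS[group_id])
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks columns {missing}")
    keep = columns + [c for c in ("growth_class",) if c in table.columns]
    return table[keep]
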