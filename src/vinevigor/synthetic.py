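"""Synthetic vineyard scene generator.

Emulates the study system the analysis pipeline expects: a steep (~30 deg)
SSW-facing slope with vine rows planted in the fall line at 2.0 m row
spacing and 1.2 m in-row spacing, a 5-band reflectance orthomosaic, DTM/DSM
pair, and stem points labeled with the six ordinal growth classes
(0, 1, 3, 5, 7, 9) at the observed field frequency distribution
206/190/343/470/402/46.

Each vine canopy is a radially tapered cap of class-dependent height H and
radius R,

    h(r) = H * cos^2(pi * r / (2 R)),   r <= R,

whose exact volume is ``H * R**2 * (pi/2 - 2/pi)`` (closed form of the polar
integral; cross-checked by quadrature in the test suite).  This analytic
truth channel enables parameter-recovery tests of the canopy-volume
estimator.  Reflectance is a per-pixel linear mixture of class-dependent
leaf endmembers and a soil endmember, weighted by local canopy cover, with
optional additive Gaussian noise, an optional NIR saturation cap (emulating
the optical saturation of dense canopies), and optional low interrow
vegetation patches (the real-world confusion source for the weakest growth
classes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .geodata import (
    BAND_ORDER,
    BandStack,
    CLASS_COLOR_CODES,
    GROWTH_CLASSES,
    GridGeoreference,
    Raster,
    VineRecord,
)

__all__ = ["SceneConfig", "SyntheticScene", "generate_dtm", "generate_scene", "bump_volume"]

#: Growth-class count distribution observed in the reference field survey.
FIELD_CLASS_COUNTS: dict[int, int] = {0: 206, 1: 190, 3: 343, 5: 470, 7: 402, 9: 46}

_DEFAULT_CLASS_PROBS = tuple(
    FIELD_CLASS_COUNTS[c] / sum(FIELD_CLASS_COUNTS.values()) for c in GROWTH_CLASSES
)

#: Leaf endmember reflectance per class, bands (blue, green, red, red_edge, nir).
#: NIR and red edge rise with vigour while red falls (denser, healthier canopy);
#: every class's pure-leaf OSAVI exceeds the 0.7 masking threshold.
DEFAULT_LEAF_REFLECTANCE_BY_CLASS: dict[int, tuple[float, ...]] = {
    1: (0.045, 0.085, 0.035, 0.36, 0.65),
    3: (0.043, 0.090, 0.035, 0.40, 0.72),
    5: (0.040, 0.095, 0.030, 0.43, 0.78),
    7: (0.038, 0.100, 0.028, 0.45, 0.85),
    9: (0.035, 0.105, 0.025, 0.46, 0.90),
}

#: Bare-soil endmember reflectance (slate-rich vineyard soil), same band order.
DEFAULT_SOIL_REFLECTANCE: tuple[float, ...] = (0.18, 0.22, 0.25, 0.28, 0.30)

#: Interrow grass endmember: green, high-OSAVI, low canopy.
GRASS_REFLECTANCE: tuple[float, ...] = (0.05, 0.12, 0.05, 0.35, 0.62)

#: The crown's optically opaque extent relative to the height-taper radius.
#: Height falls off smoothly toward R, but leaf cover ends abruptly at the
#: crown edge, so reflectance cover is a sharp disk of radius 0.9 R.
_COVER_RADIUS_FRACTION = 0.9


def bump_volume(height: float, radius: float) -> float:
    """Analytic volume of the cos^2 canopy cap (m^3)."""
    return height * radius**2 * (math.pi / 2.0 - 2.0 / math.pi)


@dataclass
class SceneConfig:
    """Parameters of a synthetic vineyard scene.

    Defaults reproduce the study conditions: ~30 deg slope, SSW aspect,
    2.0 m x 1.2 m planting grid, and the observed class frequency
    distribution.  Canopy heights/radii per class are synthetic conventions
    (no field values exist), chosen to rise monotonically with class order.
    """

    extent: tuple[float, float] = (40.0, 30.0)  # (width E-W, height N-S) in m
    pixel_size: float = 0.05
    slope_deg: float = 30.0
    aspect_deg: float = 202.5  # SSW, clockwise from north
    row_spacing: float = 2.0
    vine_spacing: float = 1.2
    class_probs: tuple[float, ...] = _DEFAULT_CLASS_PROBS
    canopy_height_by_class: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.0, 1: 0.3, 3: 0.8, 5: 1.3, 7: 1.8, 9: 2.2}
    )
    canopy_radius_by_class: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.05, 1: 0.15, 3: 0.30, 5: 0.45, 7: 0.55, 9: 0.65}
    )
    leaf_reflectance: Sequence[float] | None = None  # overrides the per-class table
    leaf_reflectance_by_class: Mapping[int, Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_LEAF_REFLECTANCE_BY_CLASS)
    )
    soil_reflectance: Sequence[float] = DEFAULT_SOIL_REFLECTANCE
    reflectance_noise_sd: float = 0.01
    #: per-vine biological variability: coefficient of variation of canopy
    #: height (radius varies at half this rate)
    canopy_size_cv: float = 0.12
    #: per-vine leaf endmember jitter SD per band (blue..nir); the NIR/red-edge
    #: spread is what makes same-class vines spectrally overlap like real ones
    leaf_reflectance_jitter_sd: tuple[float, ...] = (0.005, 0.005, 0.004, 0.015, 0.03)
    #: optional photogrammetric surface noise added to the DSM (m)
    dsm_noise_sd: float = 0.0
    nir_saturation_level: float | None = None
    interrow_vegetation_fraction: float = 0.0
    position_jitter_sd: float = 0.03
    base_elevation: float = 150.0
    origin: tuple[float, float] = (0.0, 0.0)  # SW corner (easting, northing)
    crs_code: str = "EPSG:25832"
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.asarray(self.class_probs, dtype=float)
        if probs.shape != (6,) or abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
            raise ValueError("class_probs must be 6 non-negative values summing to 1")
        if self.slope_deg >= 90.0:
            raise ValueError(f"slope_deg must be < 90, got {self.slope_deg}")
        heights = [self.canopy_height_by_class[c] for c in GROWTH_CLASSES]
        radii = [self.canopy_radius_by_class[c] for c in GROWTH_CLASSES]
        if any(h < 0 for h in heights) or any(r < 0 for r in radii):
            raise ValueError("canopy heights and radii must be non-negative")
        if any(b > a for a, b in zip(heights[1:], heights[:-1])) or any(
            b > a for a, b in zip(radii[1:], radii[:-1])
        ):
            raise ValueError("canopy heights and radii must be non-decreasing with class order")
        if not 0.0 <= self.interrow_vegetation_fraction <= 1.0:
            raise ValueError("interrow_vegetation_fraction must lie in [0, 1]")

    # -- derived geometry ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        w, h = self.extent
        return int(round(h / self.pixel_size)), int(round(w / self.pixel_size))

    def georef(self) -> GridGeoreference:
        ox, oy = self.origin
        ps = self.pixel_size
        _, height = self.extent
        # center of the NW pixel
        return GridGeoreference(ox + ps / 2.0, oy + height - ps / 2.0, ps, 0.0, self.crs_code)

    def leaf_for_class(self, growth_class: int) -> np.ndarray:
        if self.leaf_reflectance is not None:
            return np.asarray(self.leaf_reflectance, dtype=float)
        return np.asarray(self.leaf_reflectance_by_class[growth_class], dtype=float)


@dataclass
class SyntheticScene:
    """Generated scene: rasters, labeled vines, and the truth channel."""

    dtm: Raster
    dsm: Raster
    ortho: BandStack
    vines: list[VineRecord]
    truth: "object"  # pandas.DataFrame: vine_id, growth_class, true_volume, true_mean_height
    cover: Raster  # per-pixel canopy cover fraction in [0, 1]
    truth_canopy: Raster  # binary truth mask: cover >= 0.5
    config: SceneConfig


def _pixel_centers(config: SceneConfig) -> tuple[np.ndarray, np.ndarray]:
    """World coordinates (easting, northing) of every pixel center."""
    nrows, ncols = config.shape
    g = config.georef()
    east = g.origin_easting + np.arange(ncols) * g.pixel_size
    north = g.origin_northing - np.arange(nrows) * g.pixel_size
    return np.meshgrid(east, north)


def generate_dtm(config: SceneConfig) -> Raster:
    """Inclined-plane terrain: gradient magnitude tan(slope) along the aspect.

    The aspect is the azimuth of steepest *descent* (downslope direction),
    clockwise from north; elevation therefore decreases along it.
    """
    ee, nn = _pixel_centers(config)
    az = math.radians(config.aspect_deg)
    down = (math.sin(az), math.cos(az))
    grad = math.tan(math.radians(config.slope_deg))
    z = -grad * (ee * down[0] + nn * down[1])
    z -= z.min()
    z += config.base_elevation
    return Raster(z, config.georef())


def _lattice_positions(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Vine stem positions on a row lattice aligned with the fall line."""
    az = math.radians(config.aspect_deg)
    along = np.array([math.sin(az), math.cos(az)])  # rows run downslope
    across = np.array([-along[1], along[0]])
    width, height = config.extent
    cx = config.origin[0] + width / 2.0
    cy = config.origin[1] + height / 2.0
    half_diag = math.hypot(width, height) / 2.0
    margin = max(config.canopy_radius_by_class[c] for c in GROWTH_CLASSES) + 2 * config.pixel_size
    n_rows = int(half_diag / config.row_spacing) + 1
    n_along = int(half_diag / config.vine_spacing) + 1
    positions = []
    for k in range(-n_rows, n_rows + 1):
        for j in range(-n_along, n_along + 1):
            p = (
                np.array([cx, cy])
                + k * config.row_spacing * across
                + j * config.vine_spacing * along
            )
            positions.append(p)
    pos = np.array(positions)
    if config.position_jitter_sd > 0:
        pos = pos + rng.normal(0.0, config.position_jitter_sd, size=pos.shape)
    ox, oy = config.origin
    inside = (
        (pos[:, 0] >= ox + margin)
        & (pos[:, 0] <= ox + width - margin)
        & (pos[:, 1] >= oy + margin)
        & (pos[:, 1] <= oy + height - margin)
    )
    pos = pos[inside]
    # systematic numbering: sort by across-row offset then along-row offset
    order = np.lexsort((pos @ along, pos @ across))
    return pos[order]


def _cover_profile(r: np.ndarray, radius: float) -> np.ndarray:
    """Canopy cover: opaque disk out to _COVER_RADIUS_FRACTION * R."""
    return (r <= _COVER_RADIUS_FRACTION * radius).astype(float)


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Generate a complete, reproducible synthetic vineyard scene."""
    import pandas as pd

    if config.vine_spacing < 2.0 * config.pixel_size:
        raise ValueError(
            f"vine_spacing {config.vine_spacing} m < 2 x pixel_size "
            f"{config.pixel_size} m: canopies would be unresolvable"
        )
    seq = np.random.SeedSequence(config.seed)
    rng_pos, rng_class, rng_vine, rng_noise, rng_grass = (
        np.random.default_rng(s) for s in seq.spawn(5)
    )

    dtm = generate_dtm(config)
    georef = config.georef()
    nrows, ncols = config.shape
    ps = config.pixel_size

    pos = _lattice_positions(config, rng_pos)
    classes = rng_class.choice(GROWTH_CLASSES, size=len(pos), p=np.asarray(config.class_probs))

    vines = [
        VineRecord(i + 1, float(e), float(n), int(c), CLASS_COLOR_CODES[int(c)])
        for i, ((e, n), c) in enumerate(zip(pos, classes))
    ]

    ee, nn = _pixel_centers(config)
    canopy = np.zeros((nrows, ncols))
    cover = np.zeros((nrows, ncols))
    leaf = np.zeros((5, nrows, ncols))

    truth_rows = []
    jitter_sd = np.asarray(config.leaf_reflectance_jitter_sd, dtype=float)
    for rec in vines:
        cv = config.canopy_size_cv
        f_h = float(np.clip(rng_vine.normal(1.0, cv), 0.4, 1.8)) if cv > 0 else 1.0
        f_r = float(np.clip(rng_vine.normal(1.0, cv / 2.0), 0.5, 1.5)) if cv > 0 else 1.0
        spectra_offsets = rng_vine.normal(0.0, 1.0, size=5) * jitter_sd
        H = config.canopy_height_by_class[rec.growth_class] * f_h
        R = config.canopy_radius_by_class[rec.growth_class] * f_r
        volume = bump_volume(H, R) if H > 0 else 0.0
        mean_height = volume / (math.pi * R**2) if R > 0 and H > 0 else 0.0
        truth_rows.append(
            {
                "vine_id": rec.vine_id,
                "growth_class": rec.growth_class,
                "true_volume": volume,
                "true_mean_height": mean_height,
                "true_height": H if H > 0 else 0.0,
                "true_radius": R,
            }
        )
        if H <= 0 or R <= 0:
            continue
        # paint only the local window around the vine
        r0 = (georef.origin_northing - rec.northing) / ps
        c0 = (rec.easting - georef.origin_easting) / ps
        pad = int(math.ceil(R / ps)) + 1
        rr = slice(max(0, int(r0) - pad), min(nrows, int(r0) + pad + 1))
        cc = slice(max(0, int(c0) - pad), min(ncols, int(c0) + pad + 1))
        dist = np.hypot(ee[rr, cc] - rec.easting, nn[rr, cc] - rec.northing)
        inside = dist < R
        bump = np.zeros_like(dist)
        bump[inside] = H * np.cos(np.pi * dist[inside] / (2.0 * R)) ** 2
        local_cover = _cover_profile(dist, R)
        take = local_cover > cover[rr, cc]
        spectra = np.clip(config.leaf_for_class(rec.growth_class) + spectra_offsets, 0.01, 0.95)
        sub = leaf[:, rr, cc]
        sub[:, take] = spectra[:, None]
        leaf[:, rr, cc] = sub
        cover[rr, cc] = np.maximum(cover[rr, cc], local_cover)
        canopy[rr, cc] = np.maximum(canopy[rr, cc], bump)

    # interrow vegetation: low grass patches on currently bare ground
    if config.interrow_vegetation_fraction > 0:
        bare = cover < 0.05
        n_bare = int(bare.sum())
        target = int(config.interrow_vegetation_fraction * n_bare)
        patch_r = 0.30  # m
        grass = np.asarray(GRASS_REFLECTANCE)
        painted = 0
        attempts = 0
        while painted < target and attempts < 10000:
            attempts += 1
            r = rng_grass.integers(0, nrows)
            c = rng_grass.integers(0, ncols)
            if not bare[r, c]:
                continue
            pad = int(math.ceil(patch_r / ps)) + 1
            rr = slice(max(0, r - pad), min(nrows, r + pad + 1))
            cc = slice(max(0, c - pad), min(ncols, c + pad + 1))
            dist = np.hypot(ee[rr, cc] - ee[r, c], nn[rr, cc] - nn[r, c])
            patch = (dist <= patch_r) & bare[rr, cc]
            sub = leaf[:, rr, cc]
            sub[:, patch] = grass[:, None]
            leaf[:, rr, cc] = sub
            cover_sub = cover[rr, cc]
            cover_sub[patch] = 1.0
            cover[rr, cc] = cover_sub
            canopy_sub = canopy[rr, cc]
            canopy_sub[patch] = np.maximum(canopy_sub[patch], 0.08)  # <= 0.1 m grass height
            canopy[rr, cc] = canopy_sub
            bare_sub = bare[rr, cc]
            painted += int(patch.sum())
            bare_sub[patch] = False
            bare[rr, cc] = bare_sub

    surface = dtm.values + canopy
    if config.dsm_noise_sd > 0:
        surface = surface + rng_noise.normal(0.0, config.dsm_noise_sd, size=surface.shape)
    dsm = Raster(surface, georef)

    soil = np.asarray(config.soil_reflectance, dtype=float)
    bands: dict[str, Raster] = {}
    for b, role in enumerate(BAND_ORDER):
        refl = cover * leaf[b] + (1.0 - cover) * soil[b]
        if role == "nir" and config.nir_saturation_level is not None:
            refl = np.minimum(refl, config.nir_saturation_level)
        if config.reflectance_noise_sd > 0:
            refl = refl + rng_noise.normal(0.0, config.reflectance_noise_sd, size=refl.shape)
        bands[role] = Raster(np.clip(refl, 0.0, 1.0), georef)

    truth = pd.DataFrame(truth_rows).set_index("vine_id")
    return SyntheticScene(
        dtm=dtm,
        dsm=dsm,
        ortho=BandStack(bands),
        vines=vines,
        truth=truth,
        cover=Raster(cover, georef),
        truth_canopy=Raster((cover >= 0.5).astype(float), georef),
        config=config,
    )
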