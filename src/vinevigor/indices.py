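"""Vegetation-index rasters from a 5-band reflectance stack.

Six indices are supported: NDVI, NDREI, OSAVI, GNDVI, TSAVI and NDWI.  OSAVI
uses the standard soil adjustment of 0.16 in the denominator; the TSAVI soil
line (slope a, intercept b) is site-specific and not known for the reference
field, so it is free configuration with common literature defaults.

Division by zero yields nodata at the affected pixel rather than zero, so
flat-zero reflectance artifacts stay distinguishable from a true zero index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .geodata import BandStack, Raster

__all__ = ["VI_NAMES", "SoilLineParams", "compute_index", "compute_all_indices"]

#: The closed set of supported vegetation indices.
VI_NAMES: tuple[str, ...] = ("NDVI", "NDREI", "OSAVI", "GNDVI", "TSAVI", "NDWI")

_REQUIRED_BANDS: dict[str, tuple[str, ...]] = {
    "NDVI": ("nir", "red"),
    "NDREI": ("nir", "red_edge"),
    "OSAVI": ("nir", "red"),
    "GNDVI": ("nir", "green"),
    "TSAVI": ("nir", "red"),
    "NDWI": ("green", "nir"),
}


@dataclass(frozen=True)
class SoilLineParams:
    """Soil-line constants for the soil-adjusted indices."""

    osavi_adjustment: float = 0.16
    tsavi_slope: float = 1.2
    tsavi_intercept: float = 0.04
    tsavi_x: float = 0.08

    def __post_init__(self) -> None:
        if self.osavi_adjustment < 0:
            raise ValueError("osavi_adjustment must be >= 0")


def _ratio(num: np.ndarray, den: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise num/den; returns (values, zero-denominator mask)."""
    zero = den == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(zero, np.nan, num / np.where(zero, 1.0, den))
    return out, zero


def compute_index(stack: BandStack, name: str, params: SoilLineParams | None = None) -> Raster:
    """Compute one vegetation-index raster; nodata propagates from the bands."""
    params = params or SoilLineParams()
    name = name.upper()
    if name not in VI_NAMES:
        raise ValueError(f"unknown index {name!r}; supported: {VI_NAMES}")
    stack.require(_REQUIRED_BANDS[name], context=f"index {name}")

    get = lambda role: stack[role].to_masked()  # noqa: E731 - local shorthand
    if name == "NDVI":
        values, _ = _ratio(get("nir") - get("red"), get("nir") + get("red"))
    elif name == "NDREI":
        values, _ = _ratio(get("nir") - get("red_edge"), get("nir") + get("red_edge"))
    elif name == "OSAVI":
        nir, red = get("nir"), get("red")
        values, _ = _ratio(nir - red, nir + red + params.osavi_adjustment)
    elif name == "GNDVI":
        values, _ = _ratio(get("nir") - get("green"), get("nir") + get("green"))
    elif name == "NDWI":
        values, _ = _ratio(get("green") - get("nir"), get("green") + get("nir"))
    else:  # TSAVI
        a, b, x = params.tsavi_slope, params.tsavi_intercept, params.tsavi_x
        nir, red = get("nir"), get("red")
        values, _ = _ratio(a * (nir - a * red - b), a * nir + red - a * b + x * (1 + a * a))

    ref = stack[_REQUIRED_BANDS[name][0]]
    out = np.where(np.isnan(values), ref.nodata, values)
    return Raster(out, stack.georef, ref.nodata)


def compute_all_indices(stack: BandStack, params: SoilLineParams | None = None) -> dict[str, Raster]:
    """All six index rasters, shapes equal to the input stack."""
    return {name: compute_index(stack, name, params) for name in VI_NAMES}
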