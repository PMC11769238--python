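"""Canopy Height Model (CHM = DSM - DTM) and per-vine CHM volume."""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .geodata import Raster, require_coregistered

__all__ = ["compute_chm", "chm_volume"]


def compute_chm(dsm: Raster, dtm: Raster, clamp_negative: bool = True) -> Raster:
    """Canopy height as the DSM-DTM difference.

    Negative differences (terrain-model noise over bare soil) are clamped to
    zero by default since canopy height is physically non-negative; nodata in
    either input propagates.
    """
    require_coregistered(dsm, dtm, context="compute_chm")
    valid = dsm.valid_mask() & dtm.valid_mask()
    diff = dsm.values - dtm.values
    if clamp_negative:
        diff = np.maximum(diff, 0.0)
    out = np.where(valid, diff, dsm.nodata)
    return Raster(out, dsm.georef, dsm.nodata)


def chm_volume(
    chm: Raster,
    mask: Raster | None,
    pixel_set: Iterable[tuple[int, int]] | np.ndarray,
) -> float:
    """Canopy volume (m^3) = sum of height x pixel area over selected pixels.

    Pixels must be inside the raster, carry valid CHM, and (when a mask is
    given) be flagged 1 in the mask.  An empty intersection yields 0.
    """
    pixels = np.asarray(list(pixel_set) if not isinstance(pixel_set, np.ndarray) else pixel_set)
    if pixels.size == 0:
        return 0.0
    rows, cols = pixels[:, 0], pixels[:, 1]
    nrows, ncols = chm.shape
    keep = (rows >= 0) & (rows < nrows) & (cols >= 0) & (cols < ncols)
    rows, cols = rows[keep], cols[keep]
    if rows.size == 0:
        return 0.0
    select = chm.valid_mask()[rows, cols]
    if mask is not None:
        require_coregistered(chm, mask, context="chm_volume")
        select &= mask.values[rows, cols] == 1
    area = chm.pixel_size**2
    return float(np.sum(chm.values[rows[select], cols[select]]) * area)
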