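"""Haralick GLCM texture measures in a moving window.

A gray-level co-occurrence matrix counts ordered pairs of quantized gray
levels at a fixed pixel offset; eight classical measures are derived from
the normalized matrix P:

    ME  = sum x P(x,z)                     (mean)
    VAR = sum (x - ME)^2 P(x,z)            (variance)
    HOM = sum P(x,z) / (1 + (x - z)^2)     (homogeneity)
    CON = sum (x - z)^2 P(x,z)             (contrast)
    DIS = sum |x - z| P(x,z)               (dissimilarity)
    ENT = -sum P log P  over P > 0         (entropy, natural log by default)
    ASM = sum P^2                          (angular second moment)
    COR = sum (x - mu_x)(z - mu_z) P / (sigma_x sigma_z)

with mu/sigma the marginal means and population standard deviations.  The
default configuration is common Haralick practice: 32 gray levels, a 3x3
window, distance 1, all four directions (0/45/90/135 deg), symmetric
counting; all of it is configurable.

Two code paths exist: :func:`window_glcm` + :func:`texture_measures` build
the explicit matrix for one window (the definitional path), while
:func:`texture_raster` computes measures for every window of a raster
through a vectorized pair-collection scheme.  The two paths agree per pixel;
the test suite additionally checks both against a brute-force pair
enumeration oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .geodata import Raster

__all__ = [
    "GLCMConfig",
    "GLCM",
    "TextureMeasures",
    "MEASURE_NAMES",
    "quantize_band",
    "window_glcm",
    "texture_measures",
    "texture_raster",
    "texture_rasters",
]

MEASURE_NAMES: tuple[str, ...] = ("ME", "VAR", "HOM", "CON", "DIS", "ENT", "ASM", "COR")

#: direction angle (deg) -> (row offset, col offset) for unit distance
_DIRECTION_OFFSETS: dict[int, tuple[int, int]] = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}


@dataclass(frozen=True)
class GLCMConfig:
    window: int = 3
    levels: int = 32
    distance: int = 1
    directions: tuple[int, ...] = (0, 45, 90, 135)
    symmetric: bool = True
    quantization_range: tuple[float, float] | None = None  # None: auto from band
    log_base: float = math.e

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 3, got {self.window}")
        if self.levels < 2:
            raise ValueError(f"levels must be >= 2, got {self.levels}")
        if self.distance < 1:
            raise ValueError(f"distance must be >= 1, got {self.distance}")
        bad = set(self.directions) - set(_DIRECTION_OFFSETS)
        if bad:
            raise ValueError(f"unknown directions {sorted(bad)}; allowed {sorted(_DIRECTION_OFFSETS)}")

    def offsets(self) -> list[tuple[int, int]]:
        d = self.distance
        return [(dr * d, dc * d) for dr, dc in (_DIRECTION_OFFSETS[a] for a in self.directions)]


@dataclass
class GLCM:
    """Co-occurrence counts V and normalized probabilities P for one window."""

    counts: np.ndarray  # (N, N) integer ordered-pair counts
    levels: int

    @property
    def empty(self) -> bool:
        return self.counts.sum() == 0

    @property
    def P(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / total


@dataclass(frozen=True)
class TextureMeasures:
    me: float
    var: float
    hom: float
    con: float
    dis: float
    ent: float
    asm: float
    cor: float  # NaN when a marginal SD is zero

    def as_dict(self) -> dict[str, float]:
        return {
            "ME": self.me,
            "VAR": self.var,
            "HOM": self.hom,
            "CON": self.con,
            "DIS": self.dis,
            "ENT": self.ent,
            "ASM": self.asm,
            "COR": self.cor,
        }


def quantize_band(band: Raster, config: GLCMConfig) -> Raster:
    """Linear equal-width binning into levels 0..N-1; the last bin is
    upper-edge inclusive and out-of-range values are clamped.

    Nodata stays nodata (sentinel -1 in the output).  A constant band with
    auto range maps every pixel to level 0.
    """
    valid = band.valid_mask()
    values = band.values
    if config.quantization_range is not None:
        lo, hi = config.quantization_range
        if hi <= lo:
            raise ValueError(f"degenerate quantization range ({lo}, {hi})")
    else:
        if not valid.any():
            lo, hi = 0.0, 1.0
        else:
            lo, hi = float(values[valid].min()), float(values[valid].max())
    levels = np.zeros(band.shape, dtype=np.int64)
    if hi > lo:
        scaled = (values - lo) / (hi - lo) * config.levels
        levels = np.clip(np.floor(scaled), 0, config.levels - 1).astype(np.int64)
    levels[~valid] = -1
    return Raster(levels.astype(float), band.georef, nodata=-1.0)


def _level_patch(patch: np.ndarray) -> np.ndarray:
    q = np.asarray(patch)
    if q.dtype.kind == "f":
        q = np.where(np.isfinite(q), q, -1).astype(np.int64)
    return q.astype(np.int64)


def window_glcm(levels_patch: np.ndarray, config: GLCMConfig) -> GLCM:
    """Build the co-occurrence matrix of a single window patch.

    ``levels_patch`` holds quantized levels with -1 marking nodata;
    typically a ``config.window``-sided patch, but any 2-D patch is accepted
    for whole-patch statistics.  Pairs touching nodata are skipped; with
    symmetric counting each pair is counted in both orientations.
    """
    q = _level_patch(levels_patch)
    if q.ndim != 2 or min(q.shape) < 2:
        raise ValueError(f"patch must be 2-D with sides >= 2, got shape {q.shape}")
    N = config.levels
    counts = np.zeros((N, N), dtype=np.int64)
    h, w = q.shape
    for dr, dc in config.offsets():
        for r in range(max(0, -dr), h - max(0, dr)):
            for c in range(max(0, -dc), w - max(0, dc)):
                a, b = q[r, c], q[r + dr, c + dc]
                if a < 0 or b < 0:
                    continue
                counts[a, b] += 1
                if config.symmetric:
                    counts[b, a] += 1
    return GLCM(counts, N)


def texture_measures(glcm: GLCM, config: GLCMConfig | None = None) -> TextureMeasures:
    """The eight Haralick measures of a non-empty GLCM."""
    if glcm.empty:
        raise ValueError("empty GLCM: no valid pixel pair in the window")
    log_base = (config or GLCMConfig()).log_base
    P = glcm.P
    N = glcm.levels
    x = np.arange(N)[:, None]
    z = np.arange(N)[None, :]
    me = float((x * P).sum())
    var = float(((x - me) ** 2 * P).sum())
    hom = float((P / (1.0 + (x - z) ** 2)).sum())
    con = float(((x - z) ** 2 * P).sum())
    dis = float((np.abs(x - z) * P).sum())
    pos = P[P > 0]
    ent = float(-(pos * np.log(pos)).sum() / math.log(log_base))
    asm = float((P * P).sum())
    px = P.sum(axis=1)
    pz = P.sum(axis=0)
    mx = float((np.arange(N) * px).sum())
    mz = float((np.arange(N) * pz).sum())
    sx = math.sqrt(float(((np.arange(N) - mx) ** 2 * px).sum()))
    sz = math.sqrt(float(((np.arange(N) - mz) ** 2 * pz).sum()))
    if sx * sz == 0:
        cor = float("nan")
    else:
        cov = float(((x - mx) * (z - mz) * P).sum())
        cor = min(1.0, max(-1.0, cov / (sx * sz)))
    return TextureMeasures(me, var, hom, con, dis, ent, asm, cor)


# ---------------------------------------------------------------------------
# Vectorized sliding-window application
# ---------------------------------------------------------------------------

def _pair_code_planes(q: np.ndarray, config: GLCMConfig) -> np.ndarray:
    """Collect, per interior window, the codes x*N+z of every ordered pair.

    Returns an int32 array of shape (H-w+1, W-w+1, T) with -1 for pairs that
    touch nodata; T is the total ordered-pair capacity of a fully valid
    window.
    """
    from numpy.lib.stride_tricks import sliding_window_view

    N = config.levels
    w = config.window
    H, W = q.shape
    blocks: list[np.ndarray] = []
    for dr, dc in config.offsets():
        # anchor-pair code plane over the full raster
        src = q
        dst = np.full_like(q, -1)
        rs = slice(max(0, -dr), H - max(0, dr))
        cs = slice(max(0, -dc), W - max(0, dc))
        dst[rs, cs] = q[
            slice(max(0, dr), H - max(0, -dr)), slice(max(0, dc), W - max(0, -dc))
        ]
        valid = (src >= 0) & (dst >= 0)
        code = np.where(valid, src * N + dst, -1).astype(np.int32)
        rcode = np.where(valid, dst * N + src, -1).astype(np.int32)
        windows = sliding_window_view(code, (w, w))
        rwindows = sliding_window_view(rcode, (w, w))
        # anchors whose partner stays inside the window
        rsl = slice(max(0, -dr), w - max(0, dr))
        csl = slice(max(0, -dc), w - max(0, dc))
        sub = windows[:, :, rsl, csl]
        blocks.append(sub.reshape(*sub.shape[:2], -1))
        if config.symmetric:
            rsub = rwindows[:, :, rsl, csl]
            blocks.append(rsub.reshape(*rsub.shape[:2], -1))
    return np.concatenate(blocks, axis=2)


def _measures_from_codes(codes: np.ndarray, config: GLCMConfig) -> dict[str, np.ndarray]:
    """All eight measures from per-window ordered-pair code lists."""
    N = config.levels
    nwin = codes.shape[0] * codes.shape[1]
    T = codes.shape[2]
    flat = codes.reshape(nwin, T)
    valid = flat >= 0
    count = valid.sum(axis=1).astype(float)
    ok = count > 0
    safe = np.where(ok, count, 1.0)

    x = np.where(valid, flat // N, 0).astype(float)
    z = np.where(valid, flat % N, 0).astype(float)

    def mean_of(q: np.ndarray) -> np.ndarray:
        return np.where(ok, q.sum(axis=1) / safe, np.nan)

    me_x = mean_of(x)
    me_z = mean_of(z)
    var_x = mean_of(np.where(valid, (x - me_x[:, None]) ** 2, 0.0))
    var_z = mean_of(np.where(valid, (z - me_z[:, None]) ** 2, 0.0))
    d = x - z
    con = mean_of(np.where(valid, d * d, 0.0))
    dis = mean_of(np.where(valid, np.abs(d), 0.0))
    hom = mean_of(np.where(valid, 1.0 / (1.0 + d * d), 0.0))
    cov = mean_of(np.where(valid, (x - me_x[:, None]) * (z - me_z[:, None]), 0.0))
    sd = np.sqrt(var_x * var_z)
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = np.where(sd > 0, np.clip(cov / sd, -1.0, 1.0), np.nan)

    # ASM / ENT need the multiplicity of each distinct code per window
    sentinel = N * N + 1
    sorted_codes = np.sort(np.where(valid, flat, sentinel), axis=1)
    starts = np.ones_like(sorted_codes, dtype=bool)
    starts[:, 1:] = sorted_codes[:, 1:] != sorted_codes[:, :-1]
    starts &= sorted_codes != sentinel
    flat_starts = starts.ravel()
    idx = np.flatnonzero(flat_starts)
    # run end: next start in the same row, else end of the row's valid block
    row = idx // T
    row_valid_end = row * T + count[row].astype(np.int64)
    next_idx = np.empty_like(idx)
    next_idx[:-1] = idx[1:]
    next_idx[-1] = sorted_codes.size
    same_row = (next_idx // T) == row
    run_len = np.where(same_row, next_idx, row_valid_end) - idx
    p = run_len / count[row]
    asm = np.zeros(nwin)
    ent = np.zeros(nwin)
    np.add.at(asm, row, p * p)
    np.add.at(ent, row, -p * np.log(p))
    ent /= math.log(config.log_base)
    asm = np.where(ok, asm, np.nan)
    ent = np.where(ok, ent, np.nan)

    shape = codes.shape[:2]
    return {
        "ME": me_x.reshape(shape),
        "VAR": var_x.reshape(shape),
        "HOM": hom.reshape(shape),
        "CON": con.reshape(shape),
        "DIS": dis.reshape(shape),
        "ENT": ent.reshape(shape),
        "ASM": asm.reshape(shape),
        "COR": cor.reshape(shape),
    }


def texture_rasters(
    band: Raster,
    measures: Sequence[str] = MEASURE_NAMES,
    config: GLCMConfig | None = None,
    prequantized: bool = False,
) -> dict[str, Raster]:
    """Sliding-window texture rasters, co-registered with the input band.

    Border pixels whose window leaves the raster are nodata, as are windows
    without a single valid pixel pair.
    """
    config = config or GLCMConfig()
    measures = [m.upper() for m in measures]
    unknown = set(measures) - set(MEASURE_NAMES)
    if unknown:
        raise ValueError(f"unknown texture measures {sorted(unknown)}")
    q_raster = band if prequantized else quantize_band(band, config)
    q = _level_patch(q_raster.values)
    h = config.window // 2
    nodata = -9999.0
    out = {
        m: np.full(band.shape, nodata) for m in measures
    }
    if min(band.shape) >= config.window:
        codes = _pair_code_planes(q, config)
        fields = _measures_from_codes(codes, config)
        for m in measures:
            inner = fields[m]
            grid = out[m]
            grid[h : h + inner.shape[0], h : h + inner.shape[1]] = np.where(
                np.isnan(inner), nodata, inner
            )
    return {m: Raster(out[m], band.georef, nodata) for m in measures}


def texture_raster(
    band: Raster, measure: str, config: GLCMConfig | None = None, prequantized: bool = False
) -> Raster:
    """Single-measure convenience wrapper over :func:`texture_rasters`."""
    return texture_rasters(band, [measure], config, prequantized)[measure.upper()]
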