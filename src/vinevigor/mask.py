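"""Canopy-exclusive vine-row mask construction.

Two routes produce candidate masks from an index raster (OSAVI by
convention): a pixel threshold (strict ``value > t``, default t = 0.7, or an
Otsu-derived threshold), and an object-based segmentation — seeded region
growing from local maxima with Moore-8 (or von-Neumann-4) neighborhoods,
absorption of tiny segments, then k-means clustering of per-segment means
with vine clusters picked by their mean index value.  The final mask is the
intersection (logical AND) of both routes, keeping only pixels that both
agree are canopy.

The exact mechanics of GUI segmentation tools are not reproduced here; this
is a documented region-growing of equivalent structure with every setting
exposed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.filters import sobel, threshold_otsu as _skimage_otsu
from skimage.measure import label as _cc_label
from skimage.morphology import local_maxima, local_minima
from skimage.segmentation import watershed
from sklearn.cluster import KMeans

from .geodata import Raster, require_coregistered

__all__ = [
    "MaskConfig",
    "SegmentLabelRaster",
    "threshold_mask",
    "otsu_threshold",
    "segment_objects",
    "select_vine_segments",
    "fuse_masks",
    "mask_agreement",
]


@dataclass(frozen=True)
class MaskConfig:
    osavi_threshold: float = 0.7
    use_otsu: bool = False
    n_clusters: int = 6
    neighborhood: str = "moore_8"  # or "von_neumann_4"
    similarity_threshold: float = 0.0
    generalization: int = 1
    vine_cluster_selection: Sequence[int] | None = None  # None: auto by mean index
    random_state: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.neighborhood not in ("moore_8", "von_neumann_4"):
            raise ValueError(f"unknown neighborhood {self.neighborhood!r}")

    @property
    def connectivity(self) -> int:
        return 2 if self.neighborhood == "moore_8" else 1


@dataclass
class SegmentLabelRaster:
    """Segmentation result: per-pixel segment and cluster ids plus means.

    ``segments`` holds contiguous segment ids from 0 (-1 on nodata);
    ``clusters`` holds the k-means cluster id of each pixel's segment, with
    cluster ids ordered by ascending cluster mean so that id k-1 is the
    brightest cluster.  ``segment_means``/``cluster_means`` give the mean
    index value per segment / cluster.
    """

    segments: Raster
    clusters: Raster
    segment_means: np.ndarray
    segment_cluster: np.ndarray
    cluster_means: np.ndarray


def threshold_mask(index: Raster, t: float) -> Raster:
    """Binary mask: 1 where value > t (strict), 0 elsewhere, nodata preserved."""
    valid = index.valid_mask()
    out = np.where(valid, (index.values > t).astype(float), index.nodata)
    return Raster(out, index.georef, index.nodata)


def otsu_threshold(index: Raster, nbins: int = 256) -> float:
    """Histogram-based Otsu threshold over the valid pixels."""
    values = index.values[index.valid_mask()]
    if np.unique(values).size < 2:
        raise ValueError("Otsu threshold undefined for a constant raster")
    return float(_skimage_otsu(values, nbins=nbins))


def _absorb_small_segments(labels: np.ndarray, values: np.ndarray, min_size: int, connectivity: int) -> np.ndarray:
    """Merge segments of size <= min_size into the neighbor with closest mean."""
    if min_size <= 0:
        return labels
    from scipy import ndimage

    structure = ndimage.generate_binary_structure(2, connectivity)
    for _ in range(3):  # a few passes; tiny segments can cascade
        ids, sizes = np.unique(labels[labels > 0], return_counts=True)
        small = set(ids[sizes <= min_size].tolist())
        if not small:
            break
        means = ndimage.mean(values, labels=labels, index=ids)
        mean_of = dict(zip(ids.tolist(), means))
        objects = ndimage.find_objects(labels)
        for sid in small:
            sl = objects[sid - 1]
            if sl is None:
                continue
            window = tuple(
                slice(max(0, s.start - 1), min(dim, s.stop + 1))
                for s, dim in zip(sl, labels.shape)
            )
            local = labels[window]
            region = local == sid
            ring = ndimage.binary_dilation(region, structure) & ~region & (local > 0)
            neighbor_ids = np.unique(local[ring])
            if neighbor_ids.size == 0:
                continue
            best = min(
                neighbor_ids,
                key=lambda n: abs(mean_of.get(int(n), np.inf) - mean_of[int(sid)]),
            )
            local[region] = best
    return labels


def _merge_similar_segments(labels: np.ndarray, values: np.ndarray, tol: float, connectivity: int) -> np.ndarray:
    """Union adjacent segments whose mean values differ by <= tol."""
    if tol <= 0:
        return labels
    from scipy import ndimage

    ids = np.unique(labels[labels > 0])
    means = dict(zip(ids.tolist(), ndimage.mean(values, labels=labels, index=ids)))
    # adjacency via horizontal/vertical (and diagonal for Moore) label changes
    parent = {int(i): int(i) for i in ids}

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    shifts = [(0, 1), (1, 0)] + ([(1, 1), (1, -1)] if connectivity == 2 else [])
    for dr, dc in shifts:
        a = labels[max(0, -dr) : labels.shape[0] - max(0, dr), max(0, -dc) : labels.shape[1] - max(0, dc)]
        b = labels[max(0, dr) : labels.shape[0] - max(0, -dr), max(0, dc) : labels.shape[1] - max(0, -dc)]
        touching = (a > 0) & (b > 0) & (a != b)
        for pa, pb in {(int(x), int(y)) for x, y in zip(a[touching], b[touching])}:
            if abs(means[pa] - means[pb]) <= tol:
                ra, rb = find(pa), find(pb)
                if ra != rb:
                    parent[rb] = ra
    out = labels.copy()
    for i in ids:
        out[labels == i] = find(int(i))
    return out


def segment_objects(index: Raster, config: MaskConfig | None = None) -> SegmentLabelRaster:
    """Object-based segmentation of an index raster.

    Stage 1 grows regions from local-maxima seeds (watershed on the inverted
    index, Moore-8 or von-Neumann-4 connectivity), optionally merges
    adjacent segments whose means differ by at most ``similarity_threshold``
    and absorbs segments of ``generalization`` pixels or fewer.  Stage 2
    clusters per-segment mean values with deterministic k-means and relabels
    each segment by its cluster id (ids ordered by ascending cluster mean).
    """
    config = config or MaskConfig()
    valid = index.valid_mask()
    values = np.where(valid, index.values, 0.0)

    # seeds at local extrema; maxima and minima labeled separately so that
    # flat scenes (where the two sets tile the image) keep distinct markers
    maxima = local_maxima(values, connectivity=config.connectivity) & valid
    minima = local_minima(values, connectivity=config.connectivity) & valid & ~maxima
    markers = _cc_label(maxima, connectivity=config.connectivity)
    min_markers = _cc_label(minima, connectivity=config.connectivity)
    markers = np.where(min_markers > 0, min_markers + markers.max(), markers)
    # grow regions over the gradient surface: basins stay inside homogeneous
    # areas and meet at value edges, which is the similarity-driven merge the
    # segmentation is after
    gradient = sobel(values, mask=valid)
    labels = watershed(gradient, markers, mask=valid, connectivity=config.connectivity)
    labels = _merge_similar_segments(labels, values, config.similarity_threshold, config.connectivity)
    labels = _absorb_small_segments(labels, values, config.generalization, config.connectivity)

    ids = np.unique(labels[labels > 0])
    if ids.size < config.n_clusters:
        raise ValueError(
            f"{ids.size} segments found but {config.n_clusters} clusters requested; "
            "use a smaller n_clusters"
        )
    from scipy import ndimage

    seg_means = np.asarray(ndimage.mean(index.values, labels=labels, index=ids), dtype=float)

    km = KMeans(n_clusters=config.n_clusters, n_init=10, random_state=config.random_state)
    raw_cluster = km.fit_predict(seg_means.reshape(-1, 1))
    # deterministic cluster ids: ascending center value, ties by lowest raw id
    order = np.argsort(km.cluster_centers_.ravel(), kind="stable")
    remap = np.empty_like(order)
    remap[order] = np.arange(config.n_clusters)
    seg_cluster = remap[raw_cluster]

    # contiguous segment ids from 0, via a label lookup table
    lut = np.full(int(labels.max()) + 1, -1, dtype=np.int64)
    lut[ids] = np.arange(ids.size)
    seg_idx = np.where(labels > 0, lut[labels], -1)
    segments = seg_idx.astype(float)
    clusters = np.where(seg_idx >= 0, seg_cluster[np.clip(seg_idx, 0, None)], -1).astype(float)

    cluster_means = np.array(
        [index.values[(clusters == k) & valid].mean() if ((clusters == k) & valid).any() else np.nan
         for k in range(config.n_clusters)]
    )
    return SegmentLabelRaster(
        segments=Raster(segments, index.georef, -1.0),
        clusters=Raster(clusters, index.georef, -1.0),
        segment_means=seg_means,
        segment_cluster=seg_cluster,
        cluster_means=cluster_means,
    )


def select_vine_segments(
    labels: SegmentLabelRaster, index: Raster, config: MaskConfig | None = None
) -> Raster:
    """Binary mask of the vine clusters.

    Auto mode selects every cluster whose mean index exceeds the threshold,
    falling back to the single brightest cluster if none qualifies; manual
    mode takes explicit cluster ids.
    """
    config = config or MaskConfig()
    n = len(labels.cluster_means)
    if config.vine_cluster_selection is not None:
        chosen = [int(c) for c in config.vine_cluster_selection]
        missing = [c for c in chosen if c < 0 or c >= n]
        if missing:
            raise ValueError(f"cluster id(s) {missing} not present (have 0..{n - 1})")
    else:
        chosen = [k for k in range(n) if labels.cluster_means[k] > config.osavi_threshold]
        if not chosen:
            chosen = [int(np.nanargmax(labels.cluster_means))]
    member = np.isin(labels.clusters.values, chosen)
    valid = labels.clusters.values != labels.clusters.nodata
    out = np.where(valid, member.astype(float), index.nodata)
    return Raster(out, index.georef, index.nodata)


def fuse_masks(a: Raster, b: Raster, union: bool = False) -> Raster:
    """Combine two binary masks; default is the canopy-exclusive intersection."""
    require_coregistered(a, b, context="fuse_masks")
    valid = a.valid_mask() & b.valid_mask()
    if union:
        combined = (a.values == 1) | (b.values == 1)
    else:
        combined = (a.values == 1) & (b.values == 1)
    out = np.where(valid, combined.astype(float), a.nodata)
    return Raster(out, a.georef, a.nodata)


def mask_agreement(mask: Raster, reference: Raster) -> float:
    """|mask AND reference| / |reference| over valid pixels."""
    require_coregistered(mask, reference, context="mask_agreement")
    ref = (reference.values == 1) & reference.valid_mask()
    if not ref.any():
        raise ValueError("reference mask is empty")
    hit = ref & (mask.values == 1) & mask.valid_mask()
    return float(hit.sum() / ref.sum())
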