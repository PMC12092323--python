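"""Post-processing: raw segmentation map -> individual dot coordinates.

A segmentation map is binarized at a configurable grey threshold, the
watershed transform over the negated distance transform splits touching
clusters, and each surviving cluster (area >= area threshold) is reduced to
its rounded centroid.  A stricter fixed variant (5x5 circular Gaussian
pre-blur, grey threshold 148, area threshold 0) is used when harvesting
natural dots during data generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .synthgen import circular_gaussian_kernel

__all__ = [
    "DotCallConfig", "Detection", "GENERATION_VARIANT_CONFIG",
    "binarize", "call_dots", "call_dots_generation_variant", "threshold_surface",
]

_EIGHT = np.ones((3, 3), dtype=int)  # 8-connectivity structuring element


@dataclass
class DotCallConfig:
    grey_threshold: int = 254
    area_threshold: int = 0
    pre_blur: int | None = None      # odd circular-kernel size, or None

    def __post_init__(self):
        if not 0 <= self.grey_threshold <= 255:
            raise ValueError("grey_threshold must be in [0, 255]")
        if self.area_threshold < 0:
            raise ValueError("area_threshold must be >= 0")


GENERATION_VARIANT_CONFIG = DotCallConfig(grey_threshold=148, area_threshold=0,
                                          pre_blur=5)


@dataclass
class Detection:
    coords: list[tuple[int, int]]        # (x, y) integer pixels
    cluster_areas: list[int] = field(default_factory=list)

    def __len__(self):
        return len(self.coords)


def _scale_to_8bit(seg_map: np.ndarray) -> np.ndarray:
    if seg_map.ndim != 2:
        raise ValueError(f"expected a single-channel map, got shape {seg_map.shape}")
    m = np.asarray(seg_map, dtype=np.float64)
    if np.issubdtype(np.asarray(seg_map).dtype, np.floating) and m.max() <= 1.0:
        m = m * 255.0
    return m


def binarize(seg_map: np.ndarray, grey_threshold: int) -> np.ndarray:
    """Pixel positive iff its 8-bit value is strictly above the grey threshold.
    Float maps in [0, 1] are scaled by 255 first."""
    return _scale_to_8bit(seg_map) > grey_threshold


def call_dots(binary_mask: np.ndarray, area_threshold: int = 0) -> Detection:
    """Split the mask into dot clusters with the watershed transform and
    reduce each kept cluster to its rounded centroid.

    Markers are the local maxima of the Euclidean distance transform (minimum
    separation 2 px, 8-connectivity); clusters smaller than `area_threshold`
    pixels are discarded (threshold 0 keeps all).
    """
    mask = np.asarray(binary_mask).astype(bool)
    if not mask.any():
        return Detection(coords=[], cluster_areas=[])
    dist = ndimage.distance_transform_edt(mask)
    # slight smoothing turns flat distance plateaus (thin or uniform clusters)
    # into single peaks so plateaus are not split into several markers
    dist = ndimage.gaussian_filter(dist, sigma=0.7)
    peaks = peak_local_max(dist, min_distance=2, exclude_border=False, labels=mask)
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:  # degenerate: no peak found, fall back to components
        markers, _ = ndimage.label(mask, structure=_EIGHT)
    labels = watershed(-dist, markers, mask=mask, connectivity=2)

    coords: list[tuple[int, int]] = []
    areas: list[int] = []
    for lab in range(1, labels.max() + 1):
        rr, cc = np.nonzero(labels == lab)
        area = rr.size
        if area == 0 or area < area_threshold:
            continue
        y = int(np.floor(rr.mean() + 0.5))
        x = int(np.floor(cc.mean() + 0.5))
        coords.append((x, y))
        areas.append(int(area))
    return Detection(coords=coords, cluster_areas=areas)


def call_dots_generation_variant(seg_map: np.ndarray) -> Detection:
    """Fixed, highly selective pipeline used when harvesting natural dots:
    5x5 circular Gaussian blur, binarize at 148, watershed with area 0."""
    cfg = GENERATION_VARIANT_CONFIG
    m = _scale_to_8bit(seg_map)
    m = ndimage.convolve(m, circular_gaussian_kernel(cfg.pre_blur), mode="constant")
    return call_dots(binarize(m, cfg.grey_threshold), cfg.area_threshold)


def threshold_surface(maps, ground_truths, grey_range, area_range,
                      tolerance: float = 5.0):
    """F1 over a dense (grey threshold, area threshold) grid.

    For each map, dots are called once per grey value with area threshold 0;
    area filtering is then applied per candidate threshold, which is
    equivalent to re-running the watershed (the split does not depend on the
    area rule).  Returns (grid, best) with grid shape
    ``(len(grey_range), len(area_range))`` and best = (grey, area, f1); ties
    break toward smaller area, then smaller grey.
    """
    from .evalmatch import match_dots, aggregate_reports

    grey_range = list(grey_range)
    area_range = list(area_range)
    if not grey_range or not area_range:
        raise ValueError("grey_range and area_range must be non-empty")
    maps = list(maps)
    gts = [list(g) for g in ground_truths]
    if len(maps) != len(gts):
        raise ValueError("maps and ground truths must pair up")

    grid = np.zeros((len(grey_range), len(area_range)))
    for gi, grey in enumerate(grey_range):
        dets = [call_dots(binarize(m, grey), 0) for m in maps]
        for ai, area in enumerate(area_range):
            reports = []
            for det, gt in zip(dets, gts):
                kept = [c for c, a in zip(det.coords, det.cluster_areas) if a >= area]
                reports.append(match_dots(kept, gt, tolerance=tolerance))
            grid[gi, ai] = aggregate_reports(reports).f1

    best = None
    for gi, grey in enumerate(grey_range):
        for ai, area in enumerate(area_range):
            cand = (-grid[gi, ai], area, grey)   # ties: smaller area, then grey
            if best is None or cand < best:
                best = cand
    return grid, (best[2], best[1], float(-best[0]))
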