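"""Rough kidney segmentation: per-slice SKFCM pipeline and crop propagation.

One slice is segmented by: median filter -> crop to the working rectangle ->
SKFCM clustering -> keep the modal cluster -> keep its largest connected
component -> fill interior holes (excluded vessels) -> smooth the contour
morphologically -> compute the mask's minimum bounding rectangle extended by
a margin. The extended rectangle crops the adjacent slice, so one manual
rectangle on the slice with the largest kidney cross-section propagates
through the whole sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage import measure, morphology

from .io import BoundingBox, Volume, as_binary_mask, as_gray_image
from .preprocess import MedianFilterParams, median_filter
from .skfcm import SKFCMParams, SKFCMResult, skfcm_cluster

__all__ = [
    "RoughParams",
    "RoughResult",
    "crop",
    "select_max_cluster",
    "largest_connected_region",
    "fill_holes",
    "smooth_contour",
    "extended_mbr",
    "rough_segment_slice",
    "rough_segment_sequence",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RoughParams:
    """Rough-stage knobs.

    ``margin`` extends the mask's bounding rectangle before it crops the
    adjacent slice (about 10 px absorbs slice-to-slice contour drift at
    sub-millimetre slice spacing). ``smooth_radius`` is the disk radius of
    the open-then-close contour smoothing; ``max_failures`` consecutive
    flagged slices stop propagation in that direction.
    """

    margin: int = 10
    connectivity: int = 8
    smooth_radius: int = 2
    median: MedianFilterParams = field(default_factory=MedianFilterParams)
    max_failures: int = 2

    def __post_init__(self) -> None:
        if self.margin < 0 or self.smooth_radius < 0:
            raise ValueError("margin and smooth_radius must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.max_failures < 1:
            raise ValueError("max_failures must be >= 1")


@dataclass
class RoughResult:
    """Per-slice rough result: full-frame mask, crop for the next slice,
    the SKFCM labels over the crop, and failure/convergence flags."""

    mask: np.ndarray
    next_bbox: BoundingBox | None
    bbox: BoundingBox
    cluster_labels: np.ndarray | None
    converged: bool
    failed: bool
    slice_index: int = -1
    skfcm: SKFCMResult | None = None


def crop(image: np.ndarray, bbox: BoundingBox) -> np.ndarray:
    """Half-open sub-grid of the image (values equal; no view promised)."""
    img = np.asarray(image)
    bbox.validate(img.shape[:2])
    return img[bbox.slices()]


def select_max_cluster(cluster_labels: np.ndarray, centroids=None) -> np.ndarray:
    """Binary mask of the modal cluster label.

    Exact count ties are broken toward the cluster with the higher centroid
    (brighter tissue) when centroids are given, else toward the higher label
    (labels are sorted by centroid upstream).
    """
    labels = np.asarray(cluster_labels)
    if labels.size == 0:
        raise ValueError("empty label image")
    ids, counts = np.unique(labels, return_counts=True)
    best = counts == counts.max()
    candidates = ids[best]
    if centroids is not None:
        vals = np.asarray(centroids)[candidates]
        winner = candidates[int(np.argmax(vals))]
    else:
        winner = candidates.max()
    return labels == winner


def largest_connected_region(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Keep only the maximum-area connected component.

    Area ties go to the component whose top-left-most pixel comes first in
    (row, col) order. An all-zero mask is returned as-is (callers flag it).
    """
    m = as_binary_mask(mask)
    if not m.any():
        logger.warning("largest_connected_region: empty mask")
        return m.copy()
    conn = 1 if connectivity == 4 else 2
    lab = measure.label(m, connectivity=conn)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    best_area = counts.max()
    tied = np.flatnonzero(counts == best_area)
    if tied.size > 1:
        # skimage labels components in raster-scan order of first pixel,
        # so the smallest tied label is the top-left-most component.
        winner = tied.min()
    else:
        winner = tied[0]
    return lab == winner


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Set to foreground every background region not 4-connected to the border."""
    from scipy import ndimage

    m = as_binary_mask(mask)
    return ndimage.binary_fill_holes(m)  # default structure = 4-connectivity


def smooth_contour(mask: np.ndarray, radius: int) -> np.ndarray:
    """Morphological opening then closing with a disk; radius 0 is identity."""
    m = as_binary_mask(mask)
    if radius == 0:
        return m.copy()
    selem = morphology.disk(radius)
    return morphology.closing(morphology.opening(m, selem), selem).astype(bool)


def extended_mbr(mask: np.ndarray, margin: int, image_shape: tuple[int, int]) -> BoundingBox:
    """Tight bounding rectangle of the foreground, grown by ``margin`` on every
    side and clamped to the image bounds."""
    m = as_binary_mask(mask)
    rows = np.flatnonzero(m.any(axis=1))
    cols = np.flatnonzero(m.any(axis=0))
    if rows.size == 0:
        raise ValueError("empty mask has no bounding rectangle")
    r_lo, c_lo = int(rows[0]) - margin, int(cols[0]) - margin
    r_hi, c_hi = int(rows[-1]) + 1 + margin, int(cols[-1]) + 1 + margin
    return BoundingBox(max(r_lo, 0), max(c_lo, 0), r_hi, c_hi).clamp(image_shape)


def rough_segment_slice(
    image: np.ndarray,
    bbox: BoundingBox,
    skfcm_params: SKFCMParams = SKFCMParams(),
    rough_params: RoughParams = RoughParams(),
) -> RoughResult:
    """Run the six-step rough procedure on one slice.

    Returns the candidate kidney mask in full-slice coordinates plus the
    extended bounding rectangle to crop the adjacent slice. An empty
    candidate after smoothing is a flagged failure (``failed=True``), not an
    exception: the caller decides the fallback.
    """
    img = as_gray_image(image)
    bbox.validate(img.shape)
    filtered = median_filter(img, rough_params.median)
    window = crop(filtered, bbox)
    res = skfcm_cluster(window, skfcm_params)
    cand = select_max_cluster(res.labels, res.centroids)
    cand = largest_connected_region(cand, rough_params.connectivity)
    cand = fill_holes(cand)
    cand = smooth_contour(cand, rough_params.smooth_radius)
    full = np.zeros(img.shape, dtype=bool)
    full[bbox.slices()] = cand
    if not cand.any():
        logger.warning("rough segmentation produced an empty mask in %s", bbox)
        return RoughResult(
            mask=full, next_bbox=None, bbox=bbox, cluster_labels=res.labels,
            converged=res.converged, failed=True,
        )
    next_bbox = extended_mbr(full, rough_params.margin, img.shape)
    return RoughResult(
        mask=full, next_bbox=next_bbox, bbox=bbox, cluster_labels=res.labels,
        converged=res.converged, failed=False, skfcm=res,
    )


def rough_segment_sequence(
    volume: Volume,
    start_index: int,
    start_bbox: BoundingBox,
    skfcm_params: SKFCMParams = SKFCMParams(),
    rough_params: RoughParams = RoughParams(),
) -> list[RoughResult]:
    """Propagate rough segmentation bidirectionally from the seed slice.

    The seed slice (the one with the largest kidney contour, boxed manually)
    is segmented first; its extended rectangle crops both adjacent slices and
    propagation continues outward independently in each direction. A flagged
    slice reuses its predecessor's rectangle; after ``max_failures``
    consecutive failures the direction stops.

    Returns one RoughResult per processed slice, ordered by slice index.
    """
    if not (0 <= start_index < volume.n_slices):
        raise IndexError(f"start_index {start_index} out of range")
    start_bbox.validate(volume.shape)

    results: dict[int, RoughResult] = {}
    seed = rough_segment_slice(volume[start_index], start_bbox, skfcm_params, rough_params)
    seed.slice_index = start_index
    results[start_index] = seed

    for step in (+1, -1):
        prev_bbox = seed.next_bbox if seed.next_bbox is not None else start_bbox
        failures = 1 if seed.failed else 0
        i = start_index + step
        while 0 <= i < volume.n_slices and failures < rough_params.max_failures:
            r = rough_segment_slice(volume[i], prev_bbox, skfcm_params, rough_params)
            r.slice_index = i
            results[i] = r
            if r.failed:
                failures += 1  # keep the previous rectangle and try once more
            else:
                failures = 0
                prev_bbox = r.next_bbox
            i += step

    return [results[i] for i in sorted(results)]
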