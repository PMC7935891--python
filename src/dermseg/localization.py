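"""Lesion localization: from a binary mask to cropped per-lesion images.

Connected clusters of abnormal-skin pixels are traced (8-connectivity),
outlined with a contour, wrapped in a convex hull, and boxed by the hull's
axis-aligned bounding rectangle. Each box is padded, squared, and the
corresponding patch of the *original* photograph is cropped and resized for
the classifier.

Coordinates are row-major and 0-based; bounding boxes are half-open on the
max edges: (row_min, col_min, row_max, col_max).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage import measure, transform

logger = logging.getLogger(__name__)


@dataclass
class Cluster:
    """One detected lesion."""

    contour: np.ndarray               # (k, 2) ordered boundary coordinates
    hull: np.ndarray                  # (m, 2) convex hull vertices
    bbox: tuple[int, int, int, int]   # half-open (rmin, cmin, rmax, cmax)
    area: int                         # component pixel count
    centroid: tuple[float, float] = (0.0, 0.0)
    crop: np.ndarray | None = None    # (t, t, 3) uint8 after crop_and_resize
    source_id: int | None = None      # provenance for leakage-safe splitting


def _component_hull(coords: np.ndarray) -> np.ndarray:
    """Convex hull vertices of a pixel coordinate set; degenerate sets
    (points/lines, which Qhull rejects) fall back to the points themselves."""
    pts = np.unique(coords, axis=0).astype(float)
    if len(pts) < 3:
        return pts
    try:
        h = ConvexHull(pts)
        return pts[h.vertices]
    except QhullError:
        return pts


def find_clusters(mask: np.ndarray, min_area: int | None = None) -> list[Cluster]:
    """Connected components of true pixels -> clusters without crops.

    8-connectivity; components smaller than ``min_area`` (default 0.05% of
    the image) are dropped; output is ordered by (row_min, col_min).
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise ValueError(f"expected 2-d mask, got shape {mask.shape}")
    if min_area is None:
        min_area = max(1, int(round(0.0005 * mask.size)))
    labels = measure.label(mask, connectivity=2)
    clusters = []
    for region in measure.regionprops(labels):
        if region.area < min_area:
            continue
        coords = region.coords
        hull = _component_hull(coords)
        rmin, cmin = hull.min(axis=0)
        rmax, cmax = hull.max(axis=0)
        bbox = (int(rmin), int(cmin), int(rmax) + 1, int(cmax) + 1)
        comp = labels[region.slice] == region.label
        contours = measure.find_contours(np.pad(comp, 1).astype(float), 0.5)
        contour = max(contours, key=len) if contours else np.empty((0, 2))
        offset = np.array([region.bbox[0] - 1, region.bbox[1] - 1], dtype=float)
        clusters.append(Cluster(
            contour=contour + offset,
            hull=hull,
            bbox=bbox,
            area=int(region.area),
            centroid=tuple(region.centroid),
        ))
    clusters.sort(key=lambda c: (c.bbox[0], c.bbox[1]))
    return clusters


def fix_ratio(cluster: Cluster, image_shape, pad_fraction: float = 0.15) -> Cluster:
    """Pad the bbox by ``pad_fraction`` per side, then square it.

    The squared window is centered on the padded box and shifted (not
    clipped) back into the image, so the result stays square unless the
    image itself is smaller than the target side. The original bbox is
    always contained; with pad_fraction=0 the operation is idempotent.
    """
    rmin, cmin, rmax, cmax = cluster.bbox
    h_img, w_img = image_shape[:2]
    if not (0 <= rmin < rmax <= h_img and 0 <= cmin < cmax <= w_img):
        raise ValueError(f"bbox {cluster.bbox} outside image {image_shape[:2]}")
    h, w = rmax - rmin, cmax - cmin
    pr = int(round(pad_fraction * h))
    pc = int(round(pad_fraction * w))
    rmin, rmax = rmin - pr, rmax + pr
    cmin, cmax = cmin - pc, cmax + pc
    target = max(rmax - rmin, cmax - cmin)

    def _axis(lo, hi, limit):
        if target >= limit:
            return 0, limit
        center2 = lo + hi  # 2 * center, keeps arithmetic integral
        lo2 = (center2 - target) // 2
        lo2 = min(max(lo2, 0), limit - target)
        return lo2, lo2 + target

    nrmin, nrmax = _axis(rmin, rmax, h_img)
    ncmin, ncmax = _axis(cmin, cmax, w_img)
    cluster.bbox = (int(nrmin), int(ncmin), int(nrmax), int(ncmax))
    return cluster


def crop_and_resize(image: np.ndarray, cluster: Cluster, target_size: int = 64) -> Cluster:
    """Crop the bbox from the original image and resize to a square."""
    rmin, cmin, rmax, cmax = cluster.bbox
    if rmax <= rmin or cmax <= cmin:
        raise ValueError(f"empty bbox {cluster.bbox}")
    patch = np.asarray(image)[rmin:rmax, cmin:cmax]
    crop = transform.resize(patch.astype(float), (target_size, target_size),
                            order=1, preserve_range=True, anti_aliasing=False)
    cluster.crop = np.clip(np.rint(crop), 0, 255).astype(np.uint8)
    return cluster


@dataclass
class LocalizationParams:
    min_area: int | None = None   # None -> 0.05% of image pixels
    pad_fraction: float = 0.15
    target_size: int = 64


def localize(image: np.ndarray, mask: np.ndarray,
             params: LocalizationParams | None = None) -> list[Cluster]:
    """find_clusters -> fix_ratio -> crop_and_resize for every cluster."""
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape:
        raise ValueError(
            f"image {image.shape[:2]} and mask {mask.shape} dimensions differ")
    params = params or LocalizationParams()
    clusters = find_clusters(mask, params.min_area)
    if not clusters:
        logger.info("localize: no clusters above min_area in mask")
    for c in clusters:
        fix_ratio(c, image.shape, params.pad_fraction)
        crop_and_resize(image, c, params.target_size)
    return clusters
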