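"""Wing image segmentation: raster -> WingGeometry.

Coordinate convention: image origin top-left, x right, y down, in pixels;
conversion to micrometres flips y so anatomical "up" is +y.  Binarization
uses an Otsu threshold followed by a 1-px morphological closing of the vein
mask to seal hairline gaps (an automatic, documented replacement for manual
contrast curation).  Cells are the interior white connected components,
polygonized; junctions are skeleton branch points (>= 3 skeleton
neighbours) clustered within 3 px; the outline is the largest external
contour of the filled vein network.  Cells touching the image border are
discarded (cut cells at the wing base).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from .geometry import CellPolygon, WingGeometry

__all__ = ["SegmentationError", "segment_wing", "assign_sets"]


class SegmentationError(RuntimeError):
    pass


def _to_um(points_rc: np.ndarray, height: int, scale: float) -> np.ndarray:
    """(row, col) pixel coordinates -> (x, y) um with y flipped upward."""
    x = points_rc[:, 1] * scale
    y = (height - 1 - points_rc[:, 0]) * scale
    return np.column_stack([x, y])


def _largest_contour(mask: np.ndarray) -> np.ndarray:
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise SegmentationError("no contour found")
    return max(contours, key=lambda c: len(c))


def _polygonize_component(mask: np.ndarray, bbox_offset: tuple[int, int]) -> np.ndarray:
    padded = np.pad(mask, 1)
    contour = _largest_contour(padded)
    contour = contour - 1.0 + np.asarray(bbox_offset, dtype=float)
    return measure.approximate_polygon(contour, tolerance=0.5)


def _junctions_from_skeleton(skel: np.ndarray, cluster_px: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Branch-point clusters and their vein degrees.

    Degree is measured as the number of distinct skeleton branches leaving a
    ring around the cluster, which is robust to a 4-way crossing being
    skeletonized as two nearby 3-way points.
    """
    neigh = ndimage.convolve(skel.astype(np.uint8), np.ones((3, 3), dtype=np.uint8),
                             mode="constant") - skel.astype(np.uint8)
    branch = skel & (neigh >= 3)
    if not branch.any():
        return np.empty((0, 2)), np.empty(0, dtype=int)
    lab, n = ndimage.label(ndimage.binary_dilation(branch, structure=morphology.disk(cluster_px // 2 + 1)))
    centers, degrees = [], []
    for k in range(1, n + 1):
        cluster = (lab == k) & branch
        if not cluster.any():
            continue
        rc = np.argwhere(cluster)
        inner = ndimage.binary_dilation(lab == k, structure=morphology.disk(1))
        outer = ndimage.binary_dilation(lab == k, structure=morphology.disk(2))
        ring = skel & outer & ~inner
        _, nb = ndimage.label(ring, structure=np.ones((3, 3)))
        centers.append(rc.mean(axis=0))
        degrees.append(nb)
    centers = np.asarray(centers).reshape(-1, 2)
    degrees = np.asarray(degrees, dtype=int)
    keep = degrees >= 3
    return centers[keep], degrees[keep]


def segment_wing(
    image: np.ndarray,
    scale_um_per_px: float,
    side: str,
    wing_type: str,
) -> WingGeometry:
    """Extract outline, cells and junctions from a (near-)binary wing image.

    Raises :class:`SegmentationError` with "open wing boundary" when the
    vein network encloses no interior, and when no cell survives.
    """
    if scale_um_per_px <= 0:
        raise ValueError("scale must be positive")
    img = np.asarray(image)
    if img.ndim == 3:
        img = img.mean(axis=2)
    img = img.astype(float)
    if img.max() > img.min():
        thr = threshold_otsu(img)
        vein = img < thr  # dark veins
    else:
        vein = np.zeros_like(img, dtype=bool)
    vein = ndimage.binary_closing(vein, structure=morphology.disk(1))

    filled = ndimage.binary_fill_holes(vein)
    interior = filled & ~vein
    if not interior.any():
        raise SegmentationError("open wing boundary")

    h = img.shape[0]
    outline_rc = _largest_contour(filled)
    outline = _to_um(outline_rc, h, scale_um_per_px)
    outline = measure.approximate_polygon(outline, tolerance=0.5 * scale_um_per_px)

    lab, ncomp = ndimage.label(interior)
    cells = []
    cid = 0
    border_labels = set(np.unique(np.concatenate([lab[0], lab[-1], lab[:, 0], lab[:, -1]])))
    objects = ndimage.find_objects(lab)
    for k in range(1, ncomp + 1):
        if k in border_labels:
            continue  # cut cells touching the image border are discarded
        sl = objects[k - 1]
        comp = lab[sl] == k
        if comp.sum() < 4:
            continue
        poly_rc = _polygonize_component(comp, (sl[0].start, sl[1].start))
        poly = _to_um(poly_rc, h, scale_um_per_px)
        cells.append(CellPolygon(cid, poly))
        cid += 1
    if not cells:
        raise SegmentationError("zero cells detected")

    skel = morphology.skeletonize(vein)
    centers_rc, degrees = _junctions_from_skeleton(skel)
    junction_xy = _to_um(centers_rc, h, scale_um_per_px) if len(centers_rc) else np.empty((0, 2))

    return WingGeometry(
        side=side,
        wing_type=wing_type,
        outline=outline,
        cells=cells,
        junction_ids=np.arange(len(degrees)),
        junction_xy=junction_xy,
        junction_degree=degrees,
        scale_um_per_px=scale_um_per_px,
    )


def assign_sets(wing: WingGeometry, split_x: float) -> WingGeometry:
    """Label cells proximal (Set 1) / distal (Set 2) of a split abscissa.

    Cells whose centroid lies at or left of the split are Set 1; the full
    cell column containing the split (cells whose x-range straddles it) is
    included in Set 1 as well.  The split is clamped into the cells' x-range
    so a split outside the tessellation still defines a boundary column.
    """
    if not wing.cells:
        return wing
    xmins = np.array([c.vertices[:, 0].min() for c in wing.cells])
    xmaxs = np.array([c.vertices[:, 0].max() for c in wing.cells])
    lo, hi = xmins.min(), xmaxs.max()
    eps = 1e-9 * max(hi - lo, 1.0)
    s = min(max(split_x, lo + eps), hi - eps)
    from .geometry import polygon_centroid

    new_cells = []
    for c, x0, x1 in zip(wing.cells, xmins, xmaxs):
        cx = polygon_centroid(c.vertices)[0]
        label = 1 if (cx <= s or x0 < s < x1) else 2
        new_cells.append(CellPolygon(c.id, c.vertices, set_label=label))
    from dataclasses import replace

    return replace(wing, cells=new_cells)
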