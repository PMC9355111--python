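"""Region geometry: contour area, minimum enclosing circle, circularity.

A white region is an 8-connected set of pixels.  Its contour area CA is the
raw pixel count.  The minimum enclosing circular area MECA is the area of
the smallest circle containing the region, computed over the corner points
of the region's boundary pixels (so a pixel occupies its full unit square,
not just its center; this makes a 20x20 square come out at the analytic
C1 = 2/pi).  Two circularity measures are used:

    C1 = CA / MECA                  (area-based; 1 for a circle)
    C2 = 2 * sqrt(pi * CA) / P      (perimeter-based; 1 for a circle)

where P is the length of the sub-pixel (marching-squares) outer boundary,
holes filled, summed over the 4-connected sub-blobs of the region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage as ndi
from skimage import measure

__all__ = [
    "LabeledRegion",
    "compute_region_geometry",
    "regions_from_labels",
    "min_enclosing_circle_area",
    "region_perimeter",
    "mask_from_regions",
]

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class LabeledRegion:
    """Geometry of one contiguous white region.

    ``coords`` holds the absolute (row, col) pixel coordinates so that a
    mask can be rebuilt from any subset of accepted regions.
    """

    ca: int
    meca: float
    perimeter: float
    c1: float
    c2: float
    label: int = -1
    coords: np.ndarray | None = field(default=None, repr=False)


def _boundary_corner_points(mask: np.ndarray, offset: tuple[int, int] = (0, 0)) -> np.ndarray:
    """Corner points (4 per boundary pixel) of a cropped region mask."""
    if mask.sum() == 1:
        boundary = mask
    else:
        boundary = mask & ~ndi.binary_erosion(mask, structure=_EIGHT)
    rr, cc = np.nonzero(boundary)
    rr = rr.astype(float) + offset[0]
    cc = cc.astype(float) + offset[1]
    pts = np.concatenate(
        [np.stack([rr + dr, cc + dc], axis=1) for dr in (-0.5, 0.5) for dc in (-0.5, 0.5)]
    )
    return np.unique(pts, axis=0)


def min_enclosing_circle_area(points: np.ndarray) -> float:
    """Area of the smallest circle enclosing the given 2-D points."""
    radius = shapely.minimum_bounding_radius(shapely.MultiPoint(points))
    return math.pi * radius * radius


def region_perimeter(mask: np.ndarray) -> float:
    """Outer-boundary length of a cropped region mask.

    Sub-pixel marching-squares contour at level 0.5 on the hole-filled
    mask; lengths are summed over all outer contours (an 8-connected
    region may consist of several 4-connected sub-blobs).
    """
    filled = ndi.binary_fill_holes(mask)
    padded = np.pad(filled, 1).astype(float)
    total = 0.0
    for contour in measure.find_contours(padded, 0.5):
        total += float(np.sqrt((np.diff(contour, axis=0) ** 2).sum(axis=1)).sum())
    return total


def compute_region_geometry(coords: np.ndarray, label: int = -1) -> LabeledRegion:
    """Geometry of one region given its absolute (row, col) coordinates."""
    coords = np.asarray(coords)
    if coords.ndim != 2 or coords.shape[1] != 2 or len(coords) == 0:
        raise ValueError("coords must be a nonempty (N, 2) array of pixel indices")
    rmin, cmin = coords.min(axis=0)
    rmax, cmax = coords.max(axis=0)
    local = np.zeros((rmax - rmin + 1, cmax - cmin + 1), dtype=bool)
    local[coords[:, 0] - rmin, coords[:, 1] - cmin] = True

    ca = int(len(coords))
    meca = min_enclosing_circle_area(_boundary_corner_points(local))
    perimeter = region_perimeter(local)
    c1 = ca / meca
    c2 = 2.0 * math.sqrt(math.pi * ca) / perimeter if perimeter > 0 else 0.0
    return LabeledRegion(ca=ca, meca=meca, perimeter=perimeter, c1=c1, c2=c2,
                         label=label, coords=coords)


def regions_from_labels(labels: np.ndarray) -> list[LabeledRegion]:
    """Compute geometry for every labeled region in a label image."""
    regions: list[LabeledRegion] = []
    for slc, lab in zip(ndi.find_objects(labels), range(1, labels.max() + 1)):
        if slc is None:
            continue
        local = labels[slc] == lab
        rr, cc = np.nonzero(local)
        coords = np.stack([rr + slc[0].start, cc + slc[1].start], axis=1)
        regions.append(compute_region_geometry(coords, label=lab))
    return regions


def mask_from_regions(regions: list[LabeledRegion], shape: tuple[int, int]) -> np.ndarray:
    """Rebuild a boolean mask from the coordinates of the given regions."""
    mask = np.zeros(shape, dtype=bool)
    for region in regions:
        if region.coords is None:
            raise ValueError("region lacks stored coordinates")
        mask[region.coords[:, 0], region.coords[:, 1]] = True
    return mask
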