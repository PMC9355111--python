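"""Steatosis segmentation pipeline for H&E frozen-section images.

The pipeline turns one RGB biopsy image into a mask of accepted steatotic
droplets in eight steps:

1. vignette-border detection (black ring / out-of-field area excluded),
2. per-image adaptive green/blue thresholds from histogram peaks,
3. binarization (white = candidate steatosis, black = tissue),
4. morphological erosion (kills speckle noise),
5. non-tissue background rejection by area and circularity C1
   (tears, slide background, elongated vessel lumina),
6. distance-transform watershed separating clustered droplets,
7. first-pass droplet classification by area and C1, followed by
   dilation restricted to the pre-erosion white set (restores the
   boundary pixels erosion removed without inventing new ones),
8. a second watershed plus a stricter perimeter-circularity (C2) and
   area gate producing the final mask.

Area thresholds are defined for 640x480 frames at 20x magnification and
rescale linearly with image area; circularity thresholds are scale-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .config import SegmentationConfig
from .exceptions import NoTissueError
from .geometry import LabeledRegion, mask_from_regions, regions_from_labels
from .threshold import ChannelThresholds, compute_thresholds

__all__ = [
    "BinaryMask",
    "SegmentationResult",
    "detect_vignette_border",
    "binarize_image",
    "erode_binary",
    "dilate_restore",
    "watershed_separate",
    "filter_nontissue_background",
    "classify_fat_first_pass",
    "refine_second_pass",
    "segment_image",
]

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class BinaryMask:
    """Binarized image: white = candidate steatosis, black = tissue.

    ``border`` marks pixels excluded from all accounting (the black
    vignette ring and the area outside the circular field of view).
    White and border are disjoint by construction.
    """

    white: np.ndarray
    border: np.ndarray

    def __post_init__(self) -> None:
        if self.white.shape != self.border.shape:
            raise ValueError("white and border masks must share a shape")
        if bool(np.any(self.white & self.border)):
            raise ValueError("border pixels cannot be white")


@dataclass
class SegmentationResult:
    """Final droplet mask and pixel accounting for one image."""

    final_mask: np.ndarray
    border: np.ndarray
    fat_pixel_count: int
    tissue_pixel_count: int
    regions: list[LabeledRegion]
    thresholds: ChannelThresholds
    area_scale: float = 1.0
    stages: dict[str, np.ndarray] | None = None
    warnings: list[str] = field(default_factory=list)


def detect_vignette_border(
    image: np.ndarray, darkness_cutoff: int = 50, min_ring_fraction: float = 0.01
) -> np.ndarray:
    """Boolean mask of vignette-border pixels.

    A pixel belongs to the border when its maximum channel intensity is
    below ``darkness_cutoff`` and it is part of a dark component that
    either touches the image edge or forms a ring (of at least
    ``min_ring_fraction`` of the frame) enclosing the image center —
    the two geometries a microscope-ocular vignette can take.  Small dark
    interior structures (nuclei) are never border.
    """
    dark = image.max(axis=2) < darkness_cutoff
    if not dark.any():
        return np.zeros(image.shape[:2], dtype=bool)
    labels, _ = ndi.label(dark, structure=_EIGHT)
    border = np.zeros_like(dark)
    h, w = dark.shape
    edge_labels = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    edge_labels = edge_labels[edge_labels > 0]
    for lab in edge_labels:
        border |= labels == lab
    # interior ring not touching the edge: dark component whose filled
    # hull contains the image center
    center = (h // 2, w // 2)
    for slc, lab in zip(ndi.find_objects(labels), range(1, labels.max() + 1)):
        if slc is None or lab in edge_labels:
            continue
        comp = labels[slc] == lab
        if comp.sum() < min_ring_fraction * dark.size:
            continue
        if not (slc[0].start <= center[0] < slc[0].stop and slc[1].start <= center[1] < slc[1].stop):
            continue
        filled = ndi.binary_fill_holes(comp)
        if filled[center[0] - slc[0].start, center[1] - slc[1].start] and not comp[
            center[0] - slc[0].start, center[1] - slc[1].start
        ]:
            border[slc][comp] = True
    return border


def binarize_image(
    image: np.ndarray,
    thresholds: ChannelThresholds,
    border: np.ndarray | None = None,
    combine: str = "and",
) -> BinaryMask:
    """Binarize an RGB image with per-image channel thresholds.

    A non-border pixel is white when its green and blue intensities are at
    or above their thresholds (``combine="and"``, default — H&E tissue is
    pink with moderate green/blue while unstained white space is high in
    both) or when either is (``combine="or"``).
    """
    green = image[..., 1].astype(float)
    blue = image[..., 2].astype(float)
    if combine == "and":
        white = (green >= thresholds.green) & (blue >= thresholds.blue)
    elif combine == "or":
        white = (green >= thresholds.green) | (blue >= thresholds.blue)
    else:
        raise ValueError(f"combine must be 'and' or 'or', got {combine!r}")
    if border is None:
        border = np.zeros(image.shape[:2], dtype=bool)
    white &= ~border
    return BinaryMask(white=white, border=border)


def erode_binary(white: np.ndarray, kernel_size: int = 3, iterations: int = 1) -> np.ndarray:
    """Morphological erosion of the white set with a square kernel."""
    structure = np.ones((kernel_size, kernel_size), dtype=bool)
    return ndi.binary_erosion(white, structure=structure, iterations=iterations)


def dilate_restore(
    white: np.ndarray,
    pre_erosion_white: np.ndarray,
    kernel_size: int = 3,
    iterations: int = 1,
) -> np.ndarray:
    """Dilate accepted-droplet pixels, confined to the pre-erosion white set.

    Restores boundary pixels the erosion removed while guaranteeing the
    result never contains a pixel that was not white before erosion.
    """
    structure = np.ones((kernel_size, kernel_size), dtype=bool)
    dilated = ndi.binary_dilation(white, structure=structure, iterations=iterations)
    return dilated & pre_erosion_white


def watershed_separate(white: np.ndarray, min_marker_distance: int = 5) -> np.ndarray:
    """Split merged white blobs into individual regions.

    Watershed on the negated Euclidean distance transform, with markers at
    the local maxima of the distance map (minimum separation
    ``min_marker_distance``).  Every white pixel receives a label, so the
    union of the output regions equals the input white set.
    """
    labels_out = np.zeros(white.shape, dtype=np.int32)
    if not white.any():
        return labels_out
    distance = ndi.distance_transform_edt(white)
    blobs, _ = ndi.label(white, structure=_EIGHT)
    peaks = peak_local_max(
        distance, min_distance=min_marker_distance, labels=blobs, exclude_border=False
    )
    marker_mask = np.zeros(white.shape, dtype=bool)
    marker_mask[tuple(peaks.T)] = True
    markers, n_markers = ndi.label(marker_mask, structure=_EIGHT)
    if n_markers == 0:
        return blobs.astype(np.int32)
    labels_out = watershed(-distance, markers=markers, mask=white).astype(np.int32)
    # components that received no marker keep their connected-component label
    orphan = white & (labels_out == 0)
    if orphan.any():
        extra, _ = ndi.label(orphan, structure=_EIGHT)
        labels_out[orphan] = extra[orphan] + n_markers
    return labels_out


def filter_nontissue_background(
    regions: list[LabeledRegion],
    ca_hard_max: int = 2000,
    ca_soft_max: int = 600,
    c1_min: float = 0.3,
) -> list[LabeledRegion]:
    """Drop non-tissue background regions (tears, slide background, lumina).

    A region is background when CA > ``ca_hard_max`` (larger than any
    macrosteatotic droplet) or when CA > ``ca_soft_max`` with circularity
    C1 < ``c1_min`` (large and elongated).  All other regions pass
    unchanged; the operation is idempotent.
    """
    return [
        r
        for r in regions
        if not (r.ca > ca_hard_max or (r.ca > ca_soft_max and r.c1 < c1_min))
    ]


def classify_fat_first_pass(
    regions: list[LabeledRegion],
    area_min: int = 2,
    area_max: int = 1999,
    c1_min: float = 0.2,
) -> list[LabeledRegion]:
    """First-pass droplet gate: inclusive area band, strict C1 floor."""
    return [r for r in regions if area_min <= r.ca <= area_max and r.c1 > c1_min]


def _second_pass_rule(
    region: LabeledRegion, area_min: int, area_max: int, c2_min: float
) -> bool:
    """Second-pass droplet gate: inclusive area band, strict C2 floor."""
    return area_min <= region.ca <= area_max and region.c2 > c2_min


def refine_second_pass(
    white: np.ndarray,
    area_min: int = 2,
    area_max: int = 499,
    c2_min: float = 0.7,
    min_marker_distance: int = 5,
) -> tuple[np.ndarray, list[LabeledRegion]]:
    """Second watershed plus the stricter area/C2 droplet gate.

    Returns the final droplet mask and the accepted regions.  Regions kept
    satisfy ``area_min <= A <= area_max`` (inclusive) and C2 strictly above
    ``c2_min`` where C2 = 2*sqrt(pi*A)/P.
    """
    labels = watershed_separate(white, min_marker_distance=min_marker_distance)
    regions = regions_from_labels(labels)
    accepted = [r for r in regions if _second_pass_rule(r, area_min, area_max, c2_min)]
    final = mask_from_regions(accepted, white.shape)
    return final, accepted


def _ensure_rgb(image: np.ndarray) -> tuple[np.ndarray, list[str]]:
    notes: list[str] = []
    image = np.asarray(image)
    if image.ndim == 2:
        notes.append("grayscale input promoted to 3 identical channels")
        image = np.stack([image] * 3, axis=-1)
    if image.ndim != 3 or image.shape[2] < 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if image.shape[2] > 3:
        image = image[..., :3]
    if image.dtype != np.uint8:
        if image.dtype.kind in "ui" and image.max(initial=0) > 255:
            image = (image.astype(float) / 257.0).round().astype(np.uint8)
            notes.append("16-bit input rescaled to 8-bit")
        else:
            image = np.clip(image, 0, 255).astype(np.uint8)
    return image, notes


def segment_image(
    image: np.ndarray,
    config: SegmentationConfig | None = None,
    keep_stages: bool = False,
) -> SegmentationResult:
    """Run the full segmentation pipeline on one RGB biopsy image.

    Parameters
    ----------
    image : (H, W, 3) uint8 array
        RGB capture; grayscale and 16-bit inputs are promoted with a note.
    config : SegmentationConfig, optional
        All pipeline thresholds; defaults are stated for 640x480 at 20x.
    keep_stages : bool
        Store named intermediate masks in ``result.stages`` for debugging
        and overlay export.

    Raises
    ------
    NoTissueError
        If nearly the whole frame is border/black or a channel histogram
        is empty above the lower bound.
    """
    cfg = config if config is not None else SegmentationConfig()
    image, notes = _ensure_rgb(image)
    h, w = image.shape[:2]

    scale = cfg.area_scale(h, w) if cfg.rescale_thresholds else 1.0
    if (h, w) != (cfg.reference_height, cfg.reference_width) and cfg.rescale_thresholds:
        msg = (
            f"image is {w}x{h}, not {cfg.reference_width}x{cfg.reference_height}; "
            f"area thresholds rescaled by {scale:.3f}"
        )
        warnings.warn(msg, stacklevel=2)
        notes.append(msg)

    def s(value: int) -> int:
        return max(1, int(round(value * scale)))

    border = detect_vignette_border(image, cfg.darkness_cutoff)
    n_field = int((~border).sum())
    if n_field < cfg.min_tissue_fraction * border.size:
        raise NoTissueError(
            f"only {n_field} non-border pixels "
            f"({100 * n_field / border.size:.2f}% of frame)"
        )

    thresholds = compute_thresholds(
        image,
        cfg.lower_bound,
        cfg.smoothing_window,
        exclude=border,
        valley_ratio=cfg.peak_valley_ratio,
        min_peak_mass_fraction=cfg.min_peak_mass_fraction,
    )
    binary = binarize_image(image, thresholds, border, cfg.channel_combine)
    pre_erosion_white = binary.white.copy()

    eroded = erode_binary(pre_erosion_white, cfg.kernel_size, cfg.erosion_iterations)
    blobs, _ = ndi.label(eroded, structure=_EIGHT)
    kept = filter_nontissue_background(
        regions_from_labels(blobs),
        ca_hard_max=s(cfg.background_ca_hard_max),
        ca_soft_max=s(cfg.background_ca_soft_max),
        c1_min=cfg.background_c1_min,
    )
    background_filtered = mask_from_regions(kept, (h, w))

    ws_labels = watershed_separate(background_filtered, cfg.watershed_min_distance)
    first_pass = classify_fat_first_pass(
        regions_from_labels(ws_labels),
        area_min=cfg.first_pass_area_min,
        area_max=s(cfg.first_pass_area_max),
        c1_min=cfg.first_pass_c1_min,
    )
    first_pass_mask = mask_from_regions(first_pass, (h, w))

    restored = dilate_restore(
        first_pass_mask, pre_erosion_white, cfg.kernel_size, cfg.erosion_iterations
    )
    final_mask, accepted = refine_second_pass(
        restored,
        area_min=cfg.second_pass_area_min,
        area_max=s(cfg.second_pass_area_max),
        c2_min=cfg.second_pass_c2_min,
        min_marker_distance=cfg.watershed_min_distance,
    )

    fat = int(final_mask.sum())
    # tissue = stained (binarized-black, non-border) pixels plus accepted fat;
    # white pixels rejected as background/artifact stay out of the denominator
    tissue = int((~pre_erosion_white & ~border).sum()) + fat

    stages = None
    if keep_stages:
        stages = {
            "binarized": pre_erosion_white,
            "eroded": eroded,
            "background_filtered": background_filtered,
            "first_pass": first_pass_mask,
            "restored": restored,
            "final": final_mask,
        }
    return SegmentationResult(
        final_mask=final_mask,
        border=border,
        fat_pixel_count=fat,
        tissue_pixel_count=tissue,
        regions=accepted,
        thresholds=thresholds,
        area_scale=scale,
        stages=stages,
        warnings=notes,
    )
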