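"""Per-image and per-liver steatosis scores.

The per-image score is the accepted-droplet pixel count over the liver
tissue pixel count (tissue = stained pixels + accepted fat), on a 0-100
scale.  The per-liver score averages the image scores after a single
non-iterative outlier pass: scores outside mean +/- 1 sample SD are
dropped, the rest re-averaged.  Control images rendered in the
green/black/gray convention (green = fat, black = tissue, gray = neither)
are scored by direct pixel counting: 100 * green / (green + black).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import NoTissueError
from .segmentation import SegmentationResult

__all__ = [
    "SlideScore",
    "LiverScore",
    "image_steatosis_fraction",
    "liver_steatosis_score",
    "strict_estimate_from_control",
    "write_scores_csv",
    "CONTROL_GREEN",
    "CONTROL_BLACK",
    "CONTROL_GRAY",
]

# canonical control-image colors (fat / tissue / neither)
CONTROL_GREEN = np.array([0, 200, 0])
CONTROL_BLACK = np.array([0, 0, 0])
CONTROL_GRAY = np.array([128, 128, 128])


@dataclass
class SlideScore:
    """Steatosis percentage of a single image."""

    image_id: str
    steatosis_percent: float
    fat_pixels: int
    tissue_pixels: int


@dataclass
class LiverScore:
    """Aggregate score for one liver across its biopsy images."""

    liver_id: str
    image_scores: list[SlideScore]
    retained_ids: list[str]
    final_percent: float
    mean_all: float = field(default=float("nan"))
    sd_all: float = field(default=float("nan"))


def image_steatosis_fraction(result: SegmentationResult, image_id: str = "") -> SlideScore:
    """Per-image steatosis percentage from a segmentation result."""
    if result.tissue_pixel_count <= 0:
        raise NoTissueError("tissue pixel count is zero")
    percent = 100.0 * result.fat_pixel_count / result.tissue_pixel_count
    return SlideScore(
        image_id=image_id,
        steatosis_percent=percent,
        fat_pixels=result.fat_pixel_count,
        tissue_pixels=result.tissue_pixel_count,
    )


def liver_steatosis_score(scores: list[SlideScore], liver_id: str = "") -> LiverScore:
    """Mean per-image score after a single +/- 1 SD outlier omission.

    The mean m and sample standard deviation s of all image scores are
    computed once; scores inside the closed interval [m - s, m + s] are
    retained and re-averaged.  The retained set can never be empty: the
    mean of any sample lies within one SD of itself.  A single image
    returns its own score.
    """
    if not scores:
        raise ValueError("at least one image score is required")
    values = np.array([s.steatosis_percent for s in scores], dtype=float)
    if len(values) == 1:
        return LiverScore(
            liver_id=liver_id,
            image_scores=list(scores),
            retained_ids=[scores[0].image_id],
            final_percent=float(values[0]),
            mean_all=float(values[0]),
            sd_all=0.0,
        )
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    keep = (values >= mean - sd) & (values <= mean + sd)
    retained = [s for s, k in zip(scores, keep) if k]
    return LiverScore(
        liver_id=liver_id,
        image_scores=list(scores),
        retained_ids=[s.image_id for s in retained],
        final_percent=float(values[keep].mean()),
        mean_all=mean,
        sd_all=sd,
    )


def classify_control_pixels(image: np.ndarray, tolerance: int = 30) -> np.ndarray:
    """Classify control-image pixels as 0=green, 1=black, 2=gray/other.

    Pixels are assigned to the nearest of the three canonical colors; a
    pixel farther than ``tolerance`` per channel from its nearest
    canonical color counts as neither (so mildly compressed images still
    classify cleanly while off-palette pixels are excluded).
    """
    flat = image.reshape(-1, 3).astype(int)
    palette = np.stack([CONTROL_GREEN, CONTROL_BLACK, CONTROL_GRAY])
    dist = np.abs(flat[:, None, :] - palette[None, :, :]).max(axis=2)
    nearest = dist.argmin(axis=1)
    nearest[dist.min(axis=1) > tolerance] = 2
    return nearest.reshape(image.shape[:2])


def strict_estimate_from_control(control_image: np.ndarray, tolerance: int = 30) -> float:
    """Strict steatosis percentage of a green/black/gray control image.

    Returns 100 * green / (green + black); gray ("neither") pixels are
    excluded from both numerator and denominator.
    """
    if control_image.ndim != 3 or control_image.shape[2] < 3:
        raise ValueError("control image must be an (H, W, 3) RGB array")
    classes = classify_control_pixels(control_image[..., :3], tolerance)
    green = int((classes == 0).sum())
    black = int((classes == 1).sum())
    if green + black == 0:
        raise NoTissueError("control image has no green or black pixels")
    return 100.0 * green / (green + black)


def write_scores_csv(
    path: str | Path, livers: list[LiverScore]
) -> None:
    """Write per-image scores with per-liver aggregates as CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "liver_id",
                "image_id",
                "fat_pixels",
                "tissue_pixels",
                "steatosis_percent",
                "retained_flag",
                "liver_final_percent",
            ]
        )
        for liver in livers:
            retained = set(liver.retained_ids)
            for score in liver.image_scores:
                writer.writerow(
                    [
                        liver.liver_id,
                        score.image_id,
                        score.fat_pixels,
                        score.tissue_pixels,
                        f"{score.steatosis_percent:.6f}",
                        int(score.image_id in retained),
                        f"{liver.final_percent:.6f}",
                    ]
                )
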