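"""Raster image reading and mask/overlay export."""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

__all__ = ["read_image", "write_mask_png", "write_overlay_png"]

IMAGE_SUFFIXES = {".tif", ".tiff", ".png", ".jpg", ".jpeg"}


def read_image(path: str | Path) -> np.ndarray:
    """Read a TIFF/PNG/JPEG raster as an (H, W, 3) uint8 RGB array.

    16-bit inputs are rescaled to 8-bit; grayscale images are promoted to
    three identical channels with a warning; alpha channels are dropped.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        with Image.open(path) as img:
            arr = np.asarray(img.convert("RGB") if img.mode not in ("RGB", "L", "I;16") else img)
    arr = np.asarray(arr)
    if arr.ndim == 2:
        warnings.warn(f"{path.name}: grayscale image promoted to RGB", stacklevel=2)
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] > 3:
        arr = arr[..., :3]
    if arr.dtype == np.uint16:
        arr = (arr.astype(float) / 257.0).round().astype(np.uint8)
    elif arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return arr


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as an 8-bit black/white PNG."""
    Image.fromarray((mask.astype(np.uint8) * 255)).save(path)


def write_overlay_png(
    image: np.ndarray,
    mask: np.ndarray,
    path: str | Path,
    color: tuple[int, int, int] = (0, 200, 0),
    alpha: float = 0.55,
) -> None:
    """Write the original image with accepted droplets tinted ``color``."""
    overlay = image.astype(float).copy()
    tint = np.array(color, dtype=float)
    overlay[mask] = (1 - alpha) * overlay[mask] + alpha * tint
    Image.fromarray(np.clip(np.round(overlay), 0, 255).astype(np.uint8)).save(path)
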