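"""Shared fixtures and small geometric helpers."""

from __future__ import annotations

import numpy as np
import pytest


def disk_mask(shape: tuple[int, int], center: tuple[int, int], radius: float) -> np.ndarray:
    """Digital disk: pixels whose center lies within ``radius`` of ``center``."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def he_tissue_image(shape=(480, 640), color=(200, 130, 150)) -> np.ndarray:
    """Uniform pink-tissue image (no white space)."""
    img = np.empty((*shape, 3), dtype=np.uint8)
    img[...] = np.array(color, dtype=np.uint8)
    return img


def paint_white_disk(img: np.ndarray, center, radius, value=250) -> np.ndarray:
    mask = disk_mask(img.shape[:2], center, radius)
    img[mask] = value
    return mask


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
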