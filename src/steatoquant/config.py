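"""Segmentation configuration.

Every numeric constant used by the segmentation pipeline lives here, so a
run is fully described by one flat key-value mapping.  Area thresholds are
stated for the reference frame of 640x480 pixels at 20x magnification and
are rescaled linearly with image area for other frame sizes (circularity
thresholds are scale-free).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Any

__all__ = ["SegmentationConfig", "load_config"]


@dataclass
class SegmentationConfig:
    """Tunable parameters of the steatosis segmentation pipeline.

    Attributes
    ----------
    lower_bound : int
        Histogram intensity floor for peak detection.  Dark modes (nuclei,
        vignette border) fall below it; the pink-tissue and white-space
        modes lie above it and their mean becomes the channel threshold.
    smoothing_window : int
        Moving-average window (bins) applied to each channel histogram
        before peak detection, suppressing single-bin noise peaks.
    peak_valley_ratio : float
        A second histogram peak only counts as a mode when the histogram
        dips below this fraction of its height between the two peaks
        (rejects sampling-noise bumps on a unimodal flank).
    min_peak_mass_fraction : float
        Minimum smoothed peak height as a fraction of total histogram
        mass for a peak to count as a mode (a stray pixel is not a mode).
    channel_combine : str
        ``"and"`` (default): a pixel is white iff green AND blue exceed
        their thresholds.  ``"or"`` is the permissive variant.
    darkness_cutoff : int
        Pixels whose maximum channel intensity is below this value are
        candidates for the black vignette border.
    kernel_size : int
        Side of the square structuring element for erosion/dilation.
    erosion_iterations : int
        Iterations of erosion; dilation-restore mirrors this count.
    background_ca_hard_max : int
        Contour area above which a white region is always non-tissue
        background (tears, slide background).
    background_ca_soft_max, background_c1_min : int, float
        A region with contour area above the soft maximum AND circularity
        C1 below ``background_c1_min`` is non-tissue background (elongated
        vessel lumina and tears).
    first_pass_area_min, first_pass_area_max, first_pass_c1_min
        First-pass droplet gate: inclusive area band, strict C1 floor.
    second_pass_area_min, second_pass_area_max, second_pass_c2_min
        Second-pass droplet gate after the additional watershed: inclusive
        area band, strict perimeter-circularity (C2) floor.
    watershed_min_distance : int
        Minimum separation (px) between distance-transform peaks used as
        watershed markers.
    rescale_thresholds : bool
        Rescale the four area maxima by image_area / (640*480).
    min_tissue_fraction : float
        Minimum fraction of non-border pixels below which the image is
        rejected as containing no tissue.
    """

    lower_bound: int = 100
    smoothing_window: int = 5
    peak_valley_ratio: float = 0.5
    min_peak_mass_fraction: float = 1e-5
    channel_combine: str = "and"
    darkness_cutoff: int = 50
    kernel_size: int = 3
    erosion_iterations: int = 1
    background_ca_hard_max: int = 2000
    background_ca_soft_max: int = 600
    background_c1_min: float = 0.3
    first_pass_area_min: int = 2
    first_pass_area_max: int = 1999
    first_pass_c1_min: float = 0.2
    second_pass_area_min: int = 2
    second_pass_area_max: int = 499
    second_pass_c2_min: float = 0.7
    watershed_min_distance: int = 5
    rescale_thresholds: bool = True
    reference_width: int = 640
    reference_height: int = 480
    min_tissue_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.channel_combine not in ("and", "or"):
            raise ValueError(
                f"channel_combine must be 'and' or 'or', got {self.channel_combine!r}"
            )
        if not 0 <= self.lower_bound <= 254:
            raise ValueError("lower_bound must lie in [0, 254]")
        if self.kernel_size < 1 or self.smoothing_window < 1:
            raise ValueError("kernel_size and smoothing_window must be >= 1")

    @classmethod
    def from_dict(cls, mapping: dict[str, Any]) -> "SegmentationConfig":
        """Build a config from a flat mapping, rejecting unknown keys."""
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def replace(self, **overrides: Any) -> "SegmentationConfig":
        """Return a copy with the given fields overridden (unknown keys rejected)."""
        known = {f.name for f in fields(self)}
        unknown = set(overrides) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return dataclasses.replace(self, **overrides)

    def area_scale(self, height: int, width: int) -> float:
        """Linear area-threshold rescale factor for a height x width frame."""
        return (height * width) / float(self.reference_height * self.reference_width)


def load_config(path: str | Path) -> SegmentationConfig:
    """Read a config from a flat TOML, YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    suffix = path.suffix.lower()
    if suffix == ".toml":
        import tomllib

        data = tomllib.loads(text)
    elif suffix in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text)
    elif suffix == ".json":
        data = json.loads(text)
    else:
        raise ValueError(f"unsupported config format: {path.suffix!r}")
    if not isinstance(data, dict):
        raise ValueError("config file must contain a flat key-value mapping")
    return SegmentationConfig.from_dict(data)
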