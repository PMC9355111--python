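"""Per-image adaptive channel thresholds from histogram peaks.

Smartphone captures of H&E frozen sections vary widely in white balance
and exposure, so a single global threshold fails.  Instead each image gets
its own threshold per channel: the green and blue intensity histograms are
smoothed, their two highest peaks above a dark-mode lower bound are found
(pink tissue mode and white-space mode), and the threshold is the mean of
the two peak positions.  The red channel carries no discriminative signal
for H&E white space and is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .exceptions import NoTissueError

__all__ = ["ChannelThresholds", "compute_channel_threshold", "compute_thresholds"]


@dataclass(frozen=True)
class ChannelThresholds:
    """Per-image binarization thresholds for the green and blue channels."""

    green: float
    blue: float
    lower_bound: int = 100

    def __post_init__(self) -> None:
        for name, value in (("green", self.green), ("blue", self.blue)):
            if not self.lower_bound <= value <= 255:
                raise ValueError(
                    f"{name} threshold {value} outside [{self.lower_bound}, 255]"
                )


def smooth_histogram(hist: np.ndarray, window: int = 5) -> np.ndarray:
    """Moving-average smoothing; same length as the input."""
    hist = np.asarray(hist, dtype=float)
    if window <= 1:
        return hist
    kernel = np.ones(window) / window
    return np.convolve(hist, kernel, mode="same")


def compute_channel_threshold(
    histogram: np.ndarray,
    lower_bound: int = 100,
    smoothing_window: int = 5,
    valley_ratio: float = 0.5,
    min_peak_mass_fraction: float = 1e-5,
) -> float:
    """Threshold for one channel: mean of the two highest histogram peaks.

    Parameters
    ----------
    histogram : (256,) array of nonnegative bin counts
    lower_bound : int
        Bins at or below this intensity are excluded; it must sit above
        the dark modes (nuclei, border) and below the tissue mode.
    smoothing_window : int
        Moving-average window applied before peak finding.
    valley_ratio : float
        Bimodality check: the second peak only counts as a mode if the
        smoothed histogram dips below ``valley_ratio`` times that peak's
        height somewhere between the two peaks.  Sampling-noise bumps on
        the flank of a unimodal histogram have no such valley and are
        rejected, while a genuine white-space mode — however small — is
        separated from the tissue mode by a near-empty gap.
    min_peak_mass_fraction : float
        A mode must additionally reach a smoothed height of at least this
        fraction of the total histogram mass (and always more than one
        count), so a stray pixel cannot register as a mode.

    Returns
    -------
    float
        Mean intensity of the two highest local maxima above the lower
        bound; the single peak position if only one exists; the argmax of
        the restricted smoothed histogram if no interior local maximum
        exists (monotone tail).

    Raises
    ------
    NoTissueError
        If the histogram has no mass above the lower bound.
    """
    histogram = np.asarray(histogram, dtype=float)
    if histogram.shape != (256,):
        raise ValueError("histogram must have 256 bins")
    if not 0 <= lower_bound <= 254:
        raise ValueError("lower_bound must lie in [0, 254]")
    if histogram[lower_bound + 1 :].sum() == 0:
        raise NoTissueError("no histogram mass above the lower bound (empty field?)")

    smoothed = smooth_histogram(histogram, smoothing_window)
    # find_peaks handles plateau peaks (returns the plateau midpoint), which
    # smoothing of single-bin spikes produces; zero-padding lets a saturated
    # mode at intensity 255 still register as a peak.
    peak_pos, props = find_peaks(np.r_[0.0, smoothed, 0.0], height=0)
    peak_pos = peak_pos - 1
    keep = peak_pos > lower_bound
    peak_pos = peak_pos[keep]
    heights = props["peak_heights"][keep]
    floor = max(1.0, min_peak_mass_fraction * histogram.sum())
    substantial = heights >= floor
    if substantial.any():
        peak_pos = peak_pos[substantial]
        heights = heights[substantial]

    if len(peak_pos) == 0:
        # monotone above the bound: fall back to the tallest bin
        return float(lower_bound + 1 + int(np.argmax(smoothed[lower_bound + 1 :])))
    # candidates by height, ties broken toward higher intensity
    order = np.lexsort((peak_pos, heights))[::-1]
    anchor = order[0]
    for idx in order[1:]:
        lo, hi = sorted((int(peak_pos[idx]), int(peak_pos[anchor])))
        if smoothed[lo : hi + 1].min() < valley_ratio * heights[idx]:
            return float((peak_pos[anchor] + peak_pos[idx]) / 2.0)
    return float(peak_pos[anchor])


def compute_thresholds(
    image: np.ndarray,
    lower_bound: int = 100,
    smoothing_window: int = 5,
    exclude: np.ndarray | None = None,
    valley_ratio: float = 0.5,
    min_peak_mass_fraction: float = 1e-5,
) -> ChannelThresholds:
    """Adaptive green/blue thresholds for one RGB image.

    ``exclude`` is an optional boolean mask (e.g. the detected vignette
    border) of pixels left out of the histograms.
    """
    if image.ndim != 3 or image.shape[2] < 3:
        raise ValueError("image must be an (H, W, 3) RGB array")
    select = None if exclude is None else ~exclude
    thresholds = []
    for channel in (1, 2):  # green, blue
        values = image[..., channel] if select is None else image[..., channel][select]
        hist = np.bincount(values.ravel().astype(np.int64), minlength=256)[:256]
        thresholds.append(
            compute_channel_threshold(
                hist, lower_bound, smoothing_window, valley_ratio, min_peak_mass_fraction
            )
        )
    return ChannelThresholds(green=thresholds[0], blue=thresholds[1], lower_bound=lower_bound)
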