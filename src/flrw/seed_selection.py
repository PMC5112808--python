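"""Automatic seed generation from the intensity histogram.

The liver occupies a known gray-level band in contrast-enhanced CT
(roughly 125-155); the histogram mode inside that band anchors two
thresholds, s1 = peak - 3*13 and s2 = peak + 2*13 (HU offsets applied on
whatever intensity scale the image carries).  Thresholding gives a
candidate-liver mask g1 (strictly inside (s1, s2)) and a background mask
g2 (strictly below s1); both are eroded, and the largest connected
component of the eroded g1 becomes the liver seeds while all of the eroded
g2 becomes the background seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigError, SeedSelectionError
from .image_io import ImageGrid

__all__ = [
    "SeedMask",
    "LIVER",
    "BACKGROUND",
    "UNKNOWN",
    "find_liver_peak",
    "compute_thresholds",
    "threshold_masks",
    "make_seeds",
    "auto_seeds",
]

LIVER = 1
BACKGROUND = 0
UNKNOWN = -1


@dataclass
class SeedMask:
    """Ternary grid of walker boundary conditions."""

    states: np.ndarray  # int8: 1 liver seed, 0 background seed, -1 unknown

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int8)

    @property
    def shape(self):
        return self.states.shape

    @property
    def n_liver(self) -> int:
        return int((self.states == LIVER).sum())

    @property
    def n_background(self) -> int:
        return int((self.states == BACKGROUND).sum())

    def validate(self):
        if self.n_liver == 0 or self.n_background == 0:
            raise SeedSelectionError("both seed classes must be nonempty")


def find_liver_peak(image: ImageGrid | np.ndarray, search_range=(125, 155)) -> float:
    """Histogram mode within ``search_range`` after 5-bin moving-average
    smoothing of the integer-gray-level histogram; ties break to the
    highest intensity."""
    values = image.values if isinstance(image, ImageGrid) else np.asarray(image)
    lo, hi = float(search_range[0]), float(search_range[1])
    if lo >= hi:
        raise ConfigError("search_range must be (low, high) with low < high")
    rounded = np.round(values).astype(np.int64)
    gmin, gmax = int(rounded.min()), int(rounded.max())
    centers = np.arange(gmin, gmax + 1)
    counts = np.bincount((rounded - gmin).ravel(), minlength=centers.size).astype(float)
    smooth = np.convolve(counts, np.ones(5) / 5.0, mode="same")
    in_range = (centers >= lo) & (centers <= hi)
    if not in_range.any() or smooth[in_range].sum() == 0:
        raise SeedSelectionError(
            f"no histogram mass in the search range [{lo}, {hi}]; "
            "pass a custom range matching the image's intensity scale"
        )
    cand_centers = centers[in_range]
    cand_counts = smooth[in_range]
    best = cand_counts.max()
    # ties -> highest intensity
    peak = cand_centers[cand_counts >= best - 1e-12].max()
    return float(peak)


def compute_thresholds(peak: float, below: float = 3 * 13, above: float = 2 * 13):
    """Thresholds (s1, s2) = (peak - 39, peak + 26) by default."""
    if not np.isfinite(peak):
        raise ConfigError("peak must be finite")
    return float(peak) - float(below), float(peak) + float(above)


def threshold_masks(image: ImageGrid | np.ndarray, s1: float, s2: float):
    """Binary masks g1 (strictly inside (s1, s2)) and g2 (strictly below s1)."""
    if s1 >= s2:
        raise ConfigError("need s1 < s2")
    values = image.values if isinstance(image, ImageGrid) else np.asarray(image)
    g1 = (values > s1) & (values < s2)
    g2 = values < s1
    return g1, g2


def _ball(radius: int, ndim: int) -> np.ndarray:
    grids = np.ogrid[tuple(slice(-radius, radius + 1) for _ in range(ndim))]
    return sum(g**2 for g in grids) <= radius**2


def make_seeds(g1: np.ndarray, g2: np.ndarray, erosion_radius: int = 2) -> SeedMask:
    """Erode both masks, keep the largest component of g1 as liver seeds.

    Connectivity for components is 8 in 2-D / 26 in 3-D.
    """
    g1 = np.asarray(g1, dtype=bool)
    g2 = np.asarray(g2, dtype=bool)
    if erosion_radius < 0:
        raise ConfigError("erosion_radius must be >= 0")
    if erosion_radius > 0:
        selem = _ball(erosion_radius, g1.ndim)
        # liver candidates erode conservatively at the grid border; the
        # background extends beyond the grid, so its border counts as g2
        e1 = ndimage.binary_erosion(g1, structure=selem, border_value=0)
        e2 = ndimage.binary_erosion(g2, structure=selem, border_value=1)
    else:
        e1, e2 = g1, g2
    if not e1.any():
        raise SeedSelectionError("liver candidate mask empty after erosion; reduce the radius")
    if not e2.any():
        raise SeedSelectionError("background mask empty after erosion; reduce the radius")
    structure = np.ones((3,) * g1.ndim, dtype=bool)
    labels, n = ndimage.label(e1, structure=structure)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    liver = labels == np.argmax(sizes)
    states = np.full(g1.shape, UNKNOWN, dtype=np.int8)
    states[e2] = BACKGROUND
    states[liver] = LIVER  # g1 and g2 are disjoint by construction
    return SeedMask(states=states)


def auto_seeds(
    image: ImageGrid | np.ndarray,
    search_range=(125, 155),
    erosion_radius: int = 2,
    below: float = 39,
    above: float = 26,
) -> SeedMask:
    """Peak -> thresholds -> masks -> seeds, the full automatic chain.

    For 3-D volumes the peak is taken from the whole volume's histogram.
    """
    peak = find_liver_peak(image, search_range)
    s1, s2 = compute_thresholds(peak, below, above)
    g1, g2 = threshold_masks(image, s1, s2)
    seeds = make_seeds(g1, g2, erosion_radius)
    seeds.validate()
    return seeds
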