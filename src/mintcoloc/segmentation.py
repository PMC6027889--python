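"""Nucleus segmentation by auto-thresholding of the YFP channel.

The diffuse nuclear distribution of the mintbody probe is bright against
the extranuclear background, so a global auto-threshold separates the
nucleus from everything else. The threshold is found by maximizing the
between-class variance over 256 histogram-edge candidates (Otsu's
criterion, evaluated on the exact pixel values rather than binned
approximations); the binarized image is then reduced to its largest
8-connected component with holes filled, giving a single clean nucleus
mask whose interior defines the domain for the correlation analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateImageError, SegmentationError
from .images import ChannelImage

__all__ = ["NucleusMask", "auto_threshold", "segment_nucleus", "DEFAULT_MIN_AREA_PX"]

DEFAULT_MIN_AREA_PX = 50

_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class NucleusMask:
    """Binary nucleus region: one filled 8-connected component.

    ``threshold_used`` is the global intensity threshold (pixels strictly
    above it are foreground) and ``method`` names the auto-threshold
    algorithm so alternates can be recorded behind the same contract.
    """

    mask: np.ndarray
    area_px: int
    threshold_used: float
    method: str = "otsu"

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))


def auto_threshold(image: ChannelImage) -> float:
    """Global threshold maximizing between-class variance (Otsu).

    Candidate thresholds are the 256 upper bin edges of the intensity
    histogram. For each candidate t the pixels split into classes
    (<= t) and (> t); the returned threshold maximizes
    w0 * w1 * (mu0 - mu1)^2, computed on the exact pixel values. Ties are
    broken toward the lower threshold. A constant image has no separable
    classes and raises :class:`DegenerateImageError`.
    """
    px = np.sort(image.pixels, axis=None)
    lo, hi = float(px[0]), float(px[-1])
    if lo == hi:
        raise DegenerateImageError(
            "auto_threshold: constant image has no separable intensity classes"
        )
    edges = np.histogram_bin_edges(px, bins=256)
    candidates = edges[1:]  # 256 upper edges: every split is non-trivial

    n = px.size
    csum = np.concatenate(([0.0], np.cumsum(px)))
    n0 = np.searchsorted(px, candidates, side="right")
    n1 = n - n0
    total = csum[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = csum[n0] / n0
        mu1 = (total - csum[n0]) / n1
        bcv = (n0 / n) * (n1 / n) * (mu0 - mu1) ** 2
    bcv = np.where((n0 == 0) | (n1 == 0), 0.0, bcv)
    return float(candidates[int(np.argmax(bcv))])


def segment_nucleus(
    yfp: ChannelImage, min_area_px: int = DEFAULT_MIN_AREA_PX
) -> NucleusMask:
    """Segment the single nucleus in a YFP image.

    Binarizes at the auto-threshold, keeps the largest 8-connected
    component (one nucleus per image), and fills holes so locally dark
    in-nucleus pixels cannot punch holes in the correlation domain.

    Raises
    ------
    SegmentationError
        If no component of at least ``min_area_px`` pixels is found.
    DegenerateImageError
        Propagated from :func:`auto_threshold` on constant images.
    """
    threshold = auto_threshold(yfp)
    binary = yfp.pixels > threshold
    labels, n_components = ndimage.label(binary, structure=_STRUCTURE_8)
    if n_components == 0:
        raise SegmentationError("segment_nucleus: no foreground above threshold")
    counts = np.bincount(labels.ravel())[1:]
    largest = int(np.argmax(counts)) + 1
    mask = ndimage.binary_fill_holes(labels == largest)
    area = int(mask.sum())
    if area < min_area_px:
        raise SegmentationError(
            f"segment_nucleus: largest object has {area} px < min_area_px={min_area_px}"
        )
    return NucleusMask(mask=mask, area_px=area, threshold_used=threshold)
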