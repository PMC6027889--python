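"""Per-nucleus co-localization metrics.

Two complementary readouts are computed for every nucleus:

* the Pearson correlation coefficient (PCC) between the YFP and CFP
  intensities over the pixels inside the nucleus mask — positive values
  indicate co-localization of the histone-modification probe with the
  LacI-marked locus, values near zero no association;
* a binary co-localization call that operationalizes visual inspection:
  Laplacian-of-Gaussian spots are detected in both channels and the call
  is positive when a CFP (locus) spot has a YFP spot within a small
  centroid distance (default 2 px).

Restricting the PCC to the nucleus mask matters: including extranuclear
background pixels correlates the two channels through the shared nucleus
footprint and inflates r regardless of any in-nucleus association.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max

from .errors import (
    DegenerateImageError,
    ParameterError,
    SegmentationError,
    UndefinedPCCError,
)
from .images import ChannelImage, NucleusImagePair
from .segmentation import DEFAULT_MIN_AREA_PX, NucleusMask, segment_nucleus

__all__ = [
    "Spot",
    "ColocRecord",
    "AnalysisConfig",
    "pearson_cc",
    "detect_spots",
    "call_colocalization",
    "analyze_nucleus",
    "DEFAULT_SIGMAS",
]

#: LoG scales (px) spanning locus-focus size; geometric grid over 1-4 px.
DEFAULT_SIGMAS: tuple[float, ...] = tuple(float(s) for s in np.geomspace(1.0, 4.0, 4))

STATUS_OK = "ok"
STATUS_SEGMENTATION_FAILED = "segmentation_failed"
STATUS_UNDEFINED_PCC = "undefined_pcc"


@dataclass(frozen=True)
class Spot:
    """A detected fluorescent focus (sub-pixel centroid, 0-based)."""

    centroid: tuple[float, float]
    scale_sigma: float
    peak_intensity: float
    response: float
    channel_label: str


@dataclass
class ColocRecord:
    """All per-nucleus outputs of the co-localization analysis.

    ``pcc`` is None when undefined (zero in-mask variance in a channel) or
    when segmentation failed; the ``status`` field says which. Such nuclei
    are excluded from mean-PCC statistics but still counted in cohort
    frequencies (with ``coloc_call`` as computed, or False on failure).
    """

    nucleus_id: str
    group_label: str
    status: str = STATUS_OK
    pcc: Optional[float] = None
    n_mask_px: int = 0
    threshold_used: Optional[float] = None
    yfp_spots: list[Spot] = field(default_factory=list)
    cfp_spots: list[Spot] = field(default_factory=list)
    coloc_call: bool = False
    matched_pairs: list[tuple[Spot, Spot, float]] = field(default_factory=list)
    frame_index: int = 0
    timestamp_min: float = 0.0

    @property
    def min_pair_distance_px(self) -> Optional[float]:
        if not self.matched_pairs:
            return None
        return min(d for _, _, d in self.matched_pairs)


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable settings of the per-nucleus analysis."""

    min_area_px: int = DEFAULT_MIN_AREA_PX
    sigma_range: tuple[float, ...] = DEFAULT_SIGMAS
    peak_rel_threshold: float = 0.3
    d_max_px: float = 2.0
    #: when set, a match additionally requires the two spots' scales to
    #: agree within this factor ("same morphologies"); None = positional only
    scale_match_factor: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sigma_range", tuple(float(s) for s in self.sigma_range)
        )


def _mask_array(mask: Union[NucleusMask, np.ndarray]) -> np.ndarray:
    m = mask.mask if isinstance(mask, NucleusMask) else np.asarray(mask)
    return m.astype(bool)


def pearson_cc(
    yfp: ChannelImage,
    cfp: ChannelImage,
    mask: Union[NucleusMask, np.ndarray],
) -> float:
    """Pearson correlation of the two channels over the in-mask pixels.

    r = sum((Y - Ybar)(C - Cbar)) / sqrt(sum((Y - Ybar)^2) sum((C - Cbar)^2)),
    the sums running over mask pixels only. Symmetric in its channel
    arguments and invariant under per-channel positive affine transforms.

    Raises :class:`UndefinedPCCError` when either channel has zero
    variance within the mask, and :class:`ParameterError` on shape
    mismatch or a mask of fewer than 3 pixels.
    """
    m = _mask_array(mask)
    if yfp.shape != cfp.shape or m.shape != yfp.shape:
        raise ParameterError("pearson_cc: image and mask shapes must match")
    if int(m.sum()) < 3:
        raise ParameterError("pearson_cc: mask must contain at least 3 pixels")
    y = yfp.pixels[m].astype(float)
    c = cfp.pixels[m].astype(float)
    dy = y - y.mean()
    dc = c - c.mean()
    denom = math.sqrt(float(dy @ dy) * float(dc @ dc))
    if denom == 0.0:
        raise UndefinedPCCError(
            "pearson_cc: zero variance within mask in at least one channel"
        )
    return float(np.clip(float(dy @ dc) / denom, -1.0, 1.0))


def _quadratic_offset(fm: float, f0: float, fp: float) -> float:
    """Sub-pixel peak offset from a 1D quadratic fit through 3 samples."""
    denom = fm - 2.0 * f0 + fp
    if denom >= 0.0:  # not a local max along this axis; keep integer position
        return 0.0
    return float(np.clip(0.5 * (fm - fp) / denom, -0.5, 0.5))


def detect_spots(
    image: ChannelImage,
    mask: Union[NucleusMask, np.ndarray],
    sigma_range: Sequence[float] = DEFAULT_SIGMAS,
    peak_rel_threshold: float = 0.3,
) -> list[Spot]:
    """Multi-scale LoG blob detection restricted to the nucleus mask.

    Builds a scale-normalized Laplacian-of-Gaussian response stack
    (-sigma^2 * LoG), finds 3D local maxima, keeps peaks whose response is
    at least ``peak_rel_threshold`` times the maximum in-mask response,
    refines centroids to sub-pixel precision with a local quadratic fit,
    and suppresses duplicates closer than the stronger spot's scale.
    Spots are returned sorted by descending response; a flat in-mask
    image yields an empty list. Deterministic for fixed input.
    """
    sigmas = tuple(float(s) for s in sigma_range)
    if len(sigmas) == 0 or any(s <= 0 for s in sigmas):
        raise ParameterError("sigma_range: must be non-empty and positive")
    if not (0 < peak_rel_threshold <= 1):
        raise ParameterError("peak_rel_threshold: must be in (0, 1]")
    m = _mask_array(mask)
    img = image.pixels.astype(float)
    if m.shape != img.shape:
        raise ParameterError("detect_spots: image and mask shapes must match")
    in_vals = img[m]
    if in_vals.size == 0:
        return []
    in_ptp = float(in_vals.max() - in_vals.min())
    # an (effectively) flat in-mask image has no blobs to find
    if in_ptp <= 1e-12 * max(1.0, float(np.abs(img).max())):
        return []

    # subtract the in-mask mean so kernel-truncation error on the constant
    # level cannot masquerade as response; LoG itself ignores constants
    img0 = img - float(in_vals.mean())
    stack = np.stack([-(s**2) * ndimage.gaussian_laplace(img0, s) for s in sigmas])
    max_response = float(stack[:, m].max())
    if max_response <= 1e-9 * in_ptp:
        return []
    threshold = peak_rel_threshold * max_response

    peaks = peak_local_max(stack, threshold_abs=threshold, exclude_border=False)
    candidates = []
    for si, r, c in peaks:
        if not m[r, c]:
            continue
        resp = float(stack[si, r, c])
        dr = dc = 0.0
        if 0 < r < img.shape[0] - 1:
            dr = _quadratic_offset(stack[si, r - 1, c], resp, stack[si, r + 1, c])
        if 0 < c < img.shape[1] - 1:
            dc = _quadratic_offset(stack[si, r, c - 1], resp, stack[si, r, c + 1])
        candidates.append(
            Spot(
                centroid=(r + dr, c + dc),
                scale_sigma=sigmas[si],
                peak_intensity=float(img[r, c]),
                response=resp,
                channel_label=image.channel_label,
            )
        )
    candidates.sort(key=lambda s: s.response, reverse=True)

    kept: list[Spot] = []
    for spot in candidates:  # non-maximum suppression across scales
        if all(_dist(spot.centroid, k.centroid) > max(1.0, k.scale_sigma)
               for k in kept):
            kept.append(spot)
    return kept


def _dist(a: tuple[float, float], b: tuple[float, float]) -> float:
    return math.hypot(a[0] - b[0], a[1] - b[1])


def call_colocalization(
    yfp_spots: Sequence[Spot],
    cfp_spots: Sequence[Spot],
    d_max_px: float = 2.0,
    scale_match_factor: Optional[float] = None,
) -> tuple[bool, list[tuple[Spot, Spot, float]]]:
    """Binary co-localization call by greedy nearest-neighbor matching.

    Each CFP (locus) spot, in descending response order, is matched to its
    nearest unmatched YFP spot if the centroid distance is <= ``d_max_px``
    (closed boundary: exactly d_max counts as matched). The call is True
    iff at least one CFP spot is matched. With ``scale_match_factor`` set,
    a match additionally requires the spots' scale sigmas to agree within
    that factor.
    """
    if d_max_px <= 0:
        raise ParameterError("d_max_px: must be > 0")
    pairs: list[tuple[Spot, Spot, float]] = []
    unmatched = list(yfp_spots)
    for cfp in cfp_spots:
        if not unmatched:
            break
        cands = unmatched
        if scale_match_factor is not None:
            cands = [
                y for y in unmatched
                if y.scale_sigma <= scale_match_factor * cfp.scale_sigma
                and cfp.scale_sigma <= scale_match_factor * y.scale_sigma
            ]
        if not cands:
            continue
        nearest = min(cands, key=lambda y: _dist(y.centroid, cfp.centroid))
        d = _dist(nearest.centroid, cfp.centroid)
        if d <= d_max_px:
            pairs.append((cfp, nearest, d))
            unmatched.remove(nearest)
    return (len(pairs) > 0, pairs)


def analyze_nucleus(
    pair: NucleusImagePair,
    config: AnalysisConfig = AnalysisConfig(),
) -> ColocRecord:
    """Full per-nucleus analysis: segment, correlate, detect, call.

    Failures are recorded in the returned record's ``status`` — a nucleus
    is never silently dropped. Segmentation failure leaves PCC undefined
    and the call False; an undefined PCC (zero in-mask variance) still
    gets spot detection and a call.
    """
    record = ColocRecord(
        nucleus_id=pair.nucleus_id,
        group_label=pair.group_label,
        frame_index=pair.frame_index,
        timestamp_min=pair.timestamp_min,
    )
    try:
        mask = segment_nucleus(pair.yfp, min_area_px=config.min_area_px)
    except (SegmentationError, DegenerateImageError):
        record.status = STATUS_SEGMENTATION_FAILED
        return record
    record.n_mask_px = mask.area_px
    record.threshold_used = mask.threshold_used

    try:
        record.pcc = pearson_cc(pair.yfp, pair.cfp, mask)
    except UndefinedPCCError:
        record.status = STATUS_UNDEFINED_PCC

    record.yfp_spots = detect_spots(
        pair.yfp, mask, config.sigma_range, config.peak_rel_threshold
    )
    record.cfp_spots = detect_spots(
        pair.cfp, mask, config.sigma_range, config.peak_rel_threshold
    )
    record.coloc_call, record.matched_pairs = call_colocalization(
        record.yfp_spots,
        record.cfp_spots,
        d_max_px=config.d_max_px,
        scale_match_factor=config.scale_match_factor,
    )
    return record
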