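"""In-memory containers for single-nucleus two-channel images.

A nucleus is imaged as one 2D XY slice through its center in two channels:
YFP (the histone-modification mintbody, diffuse nuclear signal plus enriched
foci) and CFP (the LacI-marked locus, a single focus). Intensities are
arbitrary units stored as floats; simulated images are quantized to the
unsigned 16-bit integer grid so that disk round-trips are lossless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ParameterError

YFP = "YFP"
CFP = "CFP"


@dataclass(frozen=True)
class ChannelImage:
    """A single-channel 2D intensity raster.

    Parameters
    ----------
    pixels : (rows, cols) float array of finite, non-negative intensities.
    channel_label : "YFP" or "CFP".
    pixel_size_um : optional physical pixel size (metadata only; the
        analysis is performed in pixel units).
    """

    pixels: np.ndarray
    channel_label: str
    pixel_size_um: Optional[float] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise ParameterError("pixels: raster must be 2D and at least 2 x 2")
        if not np.all(np.isfinite(px)):
            raise ParameterError("pixels: intensities must be finite")
        if np.any(px < 0):
            raise ParameterError("pixels: intensities must be >= 0")
        if self.channel_label not in (YFP, CFP):
            raise ParameterError(
                f"channel_label: expected 'YFP' or 'CFP', got {self.channel_label!r}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class NucleusImagePair:
    """Paired YFP/CFP rasters for one nucleus plus cohort/frame metadata.

    ``truth`` is populated for simulated data only and carries the ground
    truth used by tests; real (or round-tripped) images may leave it None.
    """

    yfp: ChannelImage
    cfp: ChannelImage
    nucleus_id: str = "nucleus-000"
    group_label: str = ""
    frame_index: int = 0
    timestamp_min: float = 0.0
    truth: Optional["object"] = field(default=None, repr=False)
    sim_params: Optional["object"] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.yfp.shape != self.cfp.shape:
            raise ParameterError(
                f"channel shapes differ: YFP {self.yfp.shape} vs CFP {self.cfp.shape}"
            )
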