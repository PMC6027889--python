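"""Synthetic two-channel nuclear image generator.

The generator emulates single-nucleus confocal acquisitions of a worm
neuron expressing a fluorescent histone-modification probe (YFP channel)
together with a LacI-tagged chromosomal locus (CFP channel):

* a roughly circular nucleus of radius ``nucleus_radius`` containing a
  diffuse YFP signal of level ``yfp_nuc``;
* ``territory_count`` broad Gaussian "chromosome territory" blobs in the
  YFP channel, emulating the X-chromosome-like enrichment pattern;
* a single LacI focus (the artificial chromosome) rendered as a Gaussian
  spot of amplitude ``cfp_amplitude`` in the CFP channel;
* optional YFP co-enrichment at the locus, controlled by the dimensionless
  ``enrichment`` parameter (YFP spot amplitude = enrichment x yfp_nuc), so
  that expression-level variability cancels in the correlation expectation;
* a per-nucleus multiplicative expression factor drawn lognormally
  (probe expression differs between cells and between animals);
* Poisson shot noise (``poisson_gain`` photons per intensity unit; ``inf``
  disables it) plus zero-mean Gaussian read noise, clipped at zero.

Images are quantized to the unsigned 16-bit grid at generation time so the
TIFF round-trip is exact. All randomness flows through a single seed; the
same parameters and seed give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

from .errors import ParameterError
from .images import CFP, YFP, ChannelImage, NucleusImagePair

__all__ = [
    "NoiseModel",
    "SimParams",
    "GroundTruth",
    "expectation_rasters",
    "simulate_nucleus",
    "simulate_cohort",
    "simulate_timelapse",
    "preset_params",
    "read_sigma_for_snr",
    "PRESETS",
    "GEOMETRIES",
]


@dataclass(frozen=True)
class NoiseModel:
    """Photon (Poisson) + read (Gaussian) noise.

    poisson_gain : photons per intensity unit; ``math.inf`` disables shot
        noise (the noise-free convention used by oracle tests).
    read_sigma : standard deviation of additive Gaussian read noise, in
        intensity units; 0 disables it.
    """

    poisson_gain: float = 5.0
    read_sigma: float = 5.0

    def __post_init__(self) -> None:
        if not (self.poisson_gain > 0):
            raise ParameterError("noise_model.poisson_gain: must be > 0 (inf = off)")
        if self.read_sigma < 0:
            raise ParameterError("noise_model.read_sigma: must be >= 0")


NOISE_FREE = NoiseModel(poisson_gain=math.inf, read_sigma=0.0)


@dataclass(frozen=True)
class SimParams:
    """Full parameterization of one simulated nucleus (or time-lapse series).

    All positions are 0-based (row, col) pixel coordinates; amplitudes are
    arbitrary intensity units (a.u.).
    """

    image_size: tuple[int, int] = (128, 128)
    nucleus_center: tuple[float, float] = (64.0, 64.0)
    nucleus_radius: float = 40.0
    bg_out: float = 10.0
    yfp_nuc: float = 100.0
    expression_scale_sd: float = 0.3
    territory_count: int = 2
    territory_amplitude: float = 80.0
    territory_sigma: float = 13.0
    spot_position: Union[str, tuple[float, float]] = "random"
    spot_sigma_cfp: float = 2.0
    cfp_amplitude: float = 300.0
    enrichment: float = 0.0
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    n_frames: int = 1
    frame_interval_min: float = 30.0
    spot_step_sd: float = 1.0
    quantize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.image_size
        cr, cc = self.nucleus_center
        r = self.nucleus_radius
        if rows < 2 or cols < 2:
            raise ParameterError("image_size: must be at least 2 x 2")
        if r <= 0:
            raise ParameterError("nucleus_radius: must be > 0")
        if not (cr - r >= 0 and cr + r <= rows - 1 and cc - r >= 0 and cc + r <= cols - 1):
            raise ParameterError(
                "nucleus_center/nucleus_radius: nucleus must fit inside the image"
            )
        for name in ("bg_out", "yfp_nuc", "expression_scale_sd", "territory_amplitude",
                     "territory_sigma", "spot_sigma_cfp", "cfp_amplitude", "enrichment",
                     "spot_step_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name}: must be >= 0")
        if self.territory_count < 0:
            raise ParameterError("territory_count: must be >= 0")
        if self.spot_sigma_cfp == 0:
            raise ParameterError("spot_sigma_cfp: must be > 0")
        if isinstance(self.spot_position, str):
            if self.spot_position != "random":
                raise ParameterError("spot_position: expected (row, col) or 'random'")
        else:
            sr, sc = self.spot_position
            if (sr - cr) ** 2 + (sc - cc) ** 2 > r**2:
                raise ParameterError("spot_position: must lie inside the nucleus disk")
        if self.n_frames < 1:
            raise ParameterError("n_frames: must be >= 1")
        if self.frame_interval_min <= 0:
            raise ParameterError("frame_interval_min: must be > 0")


@dataclass
class GroundTruth:
    """Everything the simulator knows that the analysis must recover."""

    true_mask: np.ndarray
    spot_position: tuple[float, float]
    enrichment_used: float
    expression_factor: float
    territory_centers: list[tuple[float, float]]
    spot_positions_per_frame: Optional[list[tuple[float, float]]] = None
    timestamps_min: Optional[list[float]] = None


def read_sigma_for_snr(params: SimParams, snr: float) -> float:
    """Read-noise sigma giving the requested in-nucleus SNR.

    SNR is defined as (diffuse in-nucleus YFP level - extranuclear
    background) / noise sd, assuming shot noise is disabled.
    """
    if snr <= 0:
        raise ParameterError("snr: must be > 0")
    return (params.yfp_nuc - params.bg_out) / snr


def _disk_mask(image_size: tuple[int, int], center: tuple[float, float],
               radius: float) -> np.ndarray:
    rows, cols = image_size
    rr, cc = np.mgrid[0:rows, 0:cols]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _gaussian(image_size: tuple[int, int], center: tuple[float, float],
              sigma: float) -> np.ndarray:
    rows, cols = image_size
    rr, cc = np.mgrid[0:rows, 0:cols]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    return np.exp(-d2 / (2.0 * sigma**2))


def expectation_rasters(
    params: SimParams,
    spot_position: tuple[float, float],
    territory_centers: Sequence[tuple[float, float]],
    expression_factor: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noise-free expected YFP and CFP rasters plus the true nucleus mask.

    YFP: ``bg_out`` outside the nucleus; inside,
    ``expression_factor * (yfp_nuc + sum of territory Gaussians +
    enrichment * yfp_nuc * G(spot))``.
    CFP: ``bg_out`` everywhere plus ``cfp_amplitude * G(spot)``.
    """
    mask = _disk_mask(params.image_size, params.nucleus_center, params.nucleus_radius)
    spot_g = _gaussian(params.image_size, spot_position, params.spot_sigma_cfp)

    yfp_in = np.full(params.image_size, params.yfp_nuc, dtype=float)
    for tc in territory_centers:
        yfp_in += params.territory_amplitude * _gaussian(
            params.image_size, tc, params.territory_sigma
        )
    yfp_in += params.enrichment * params.yfp_nuc * spot_g
    yfp = np.where(mask, expression_factor * yfp_in, params.bg_out)

    cfp = params.bg_out + params.cfp_amplitude * spot_g
    return yfp, cfp, mask


def _apply_noise(expect: np.ndarray, noise: NoiseModel, rng: np.random.Generator,
                 quantize: bool) -> np.ndarray:
    img = expect
    if math.isfinite(noise.poisson_gain):
        img = rng.poisson(img * noise.poisson_gain) / noise.poisson_gain
    if noise.read_sigma > 0:
        img = img + rng.normal(0.0, noise.read_sigma, size=img.shape)
    img = np.clip(img, 0.0, None)
    if quantize:
        img = np.clip(np.round(img), 0.0, 65535.0)
    return np.asarray(img, dtype=float)


def _uniform_in_disk(rng: np.random.Generator, center: tuple[float, float],
                     radius: float) -> tuple[float, float]:
    # area-uniform draw: radius ~ sqrt(U) * R
    r = radius * math.sqrt(rng.uniform())
    theta = rng.uniform(0.0, 2.0 * math.pi)
    return (center[0] + r * math.sin(theta), center[1] + r * math.cos(theta))


def _draw_latents(params: SimParams, rng: np.random.Generator):
    """Draw per-nucleus latent variables in a fixed order (determinism)."""
    if params.expression_scale_sd > 0:
        expression_factor = float(np.exp(rng.normal(0.0, params.expression_scale_sd)))
    else:
        expression_factor = 1.0
    # territory centers are uniform over the whole nucleus disk: a blob may
    # straddle the rim (it is clipped by the nucleus), and the expected
    # territory field stays flat enough that an unrelated locus spot shows
    # no spurious correlation with it
    territory_centers = [
        _uniform_in_disk(rng, params.nucleus_center, params.nucleus_radius)
        for _ in range(params.territory_count)
    ]
    if isinstance(params.spot_position, str):
        # keep the focus away from the rim so the whole spot stays nuclear
        spot = _uniform_in_disk(
            rng, params.nucleus_center,
            max(params.nucleus_radius - 3.0 * params.spot_sigma_cfp, 1.0),
        )
    else:
        spot = (float(params.spot_position[0]), float(params.spot_position[1]))
    return expression_factor, territory_centers, spot


def _make_pair(params: SimParams, yfp_px: np.ndarray, cfp_px: np.ndarray,
               nucleus_id: str, group_label: str, frame_index: int,
               timestamp_min: float, truth: GroundTruth) -> NucleusImagePair:
    return NucleusImagePair(
        yfp=ChannelImage(yfp_px, YFP),
        cfp=ChannelImage(cfp_px, CFP),
        nucleus_id=nucleus_id,
        group_label=group_label,
        frame_index=frame_index,
        timestamp_min=timestamp_min,
        truth=truth,
        sim_params=params,
    )


def simulate_nucleus(
    params: SimParams,
    nucleus_id: str = "nucleus-000",
    group_label: str = "",
) -> tuple[NucleusImagePair, GroundTruth]:
    """Simulate a single two-channel nucleus image with ground truth."""
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    expression_factor, territory_centers, spot = _draw_latents(params, rng)
    yfp_e, cfp_e, mask = expectation_rasters(
        params, spot, territory_centers, expression_factor
    )
    yfp_px = _apply_noise(yfp_e, params.noise_model, rng, params.quantize)
    cfp_px = _apply_noise(cfp_e, params.noise_model, rng, params.quantize)
    truth = GroundTruth(
        true_mask=mask,
        spot_position=spot,
        enrichment_used=params.enrichment,
        expression_factor=expression_factor,
        territory_centers=territory_centers,
    )
    pair = _make_pair(params, yfp_px, cfp_px, nucleus_id, group_label, 0, 0.0, truth)
    return pair, truth


def child_seed(master_seed: int, group_index: int, nucleus_index: int) -> int:
    """Derive a collision-free per-nucleus seed from the master seed."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(group_index, nucleus_index))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def simulate_cohort(
    group_specs: Sequence[tuple[str, SimParams, int]],
    seed: int,
) -> list[NucleusImagePair]:
    """Simulate labelled cohorts of nuclei.

    Each group is (label, params, n_nuclei); per-nucleus seeds are derived
    from ``seed`` via a splittable counter scheme, so cohorts are
    reproducible and seed collisions across nuclei cannot occur. Expression
    factors are i.i.d. lognormal across nuclei.
    """
    if len(group_specs) == 0:
        raise ParameterError("group_specs: at least one group is required")
    pairs: list[NucleusImagePair] = []
    for gi, (label, params, n_nuclei) in enumerate(group_specs):
        if n_nuclei < 1:
            raise ParameterError(f"n_nuclei: must be >= 1 (group {label!r})")
        for ni in range(n_nuclei):
            p = replace(params, seed=child_seed(seed, gi, ni))
            pair, _ = simulate_nucleus(
                p, nucleus_id=f"{label}-{ni:03d}", group_label=label
            )
            pairs.append(pair)
    return pairs


def _reflect_radial(pos: tuple[float, float], center: tuple[float, float],
                    radius: float) -> tuple[float, float]:
    """Fold a position back inside the disk by radial reflection."""
    dr, dc = pos[0] - center[0], pos[1] - center[1]
    d = math.hypot(dr, dc)
    if d <= radius or d == 0.0:
        return pos
    # reflect the radial coordinate at the boundary, repeatedly if needed
    period = 2.0 * radius
    folded = d % period
    if folded > radius:
        folded = period - folded
    scale = folded / d
    return (center[0] + dr * scale, center[1] + dc * scale)


def simulate_timelapse(
    params: SimParams,
    nucleus_id: str = "nucleus-000",
    group_label: str = "",
) -> tuple[list[NucleusImagePair], GroundTruth]:
    """Simulate a time-lapse series of one nucleus.

    The locus performs a bounded Gaussian random walk (step sd
    ``spot_step_sd`` px/frame) reflected at the nucleus boundary; nucleus,
    territories and expression factor are fixed across frames; noise is
    independent per frame. Timestamps are ``frame_interval_min * index``
    minutes (the default acquisition, 11 frames at 30-min intervals, spans
    0-300 min).
    """
    if params.n_frames < 2:
        raise ParameterError("n_frames: time-lapse requires n_frames >= 2")
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    expression_factor, territory_centers, spot = _draw_latents(params, rng)

    walk_radius = max(params.nucleus_radius - 3.0 * params.spot_sigma_cfp, 1.0)
    positions = [spot]
    for _ in range(params.n_frames - 1):
        step = rng.normal(0.0, params.spot_step_sd, size=2) if params.spot_step_sd > 0 \
            else np.zeros(2)
        nxt = (positions[-1][0] + float(step[0]), positions[-1][1] + float(step[1]))
        positions.append(_reflect_radial(nxt, params.nucleus_center, walk_radius))

    timestamps = [params.frame_interval_min * i for i in range(params.n_frames)]
    mask = _disk_mask(params.image_size, params.nucleus_center, params.nucleus_radius)
    truth = GroundTruth(
        true_mask=mask,
        spot_position=spot,
        enrichment_used=params.enrichment,
        expression_factor=expression_factor,
        territory_centers=territory_centers,
        spot_positions_per_frame=positions,
        timestamps_min=timestamps,
    )
    frames: list[NucleusImagePair] = []
    for i, (pos, t) in enumerate(zip(positions, timestamps)):
        yfp_e, cfp_e, _ = expectation_rasters(
            params, pos, territory_centers, expression_factor
        )
        yfp_px = _apply_noise(yfp_e, params.noise_model, rng, params.quantize)
        cfp_px = _apply_noise(cfp_e, params.noise_model, rng, params.quantize)
        frames.append(
            _make_pair(params, yfp_px, cfp_px, nucleus_id, group_label, i, t, truth)
        )
    return frames, truth


# ---------------------------------------------------------------------------
# presets

#: YFP enrichment level at the LacI focus per experimental condition.
#: Chosen to reproduce the qualitative ordering of the published contrasts:
#: modification-recruiting sequences (her-1, rex-1) give strongly positive
#: per-nucleus correlations, the operator-only and male conditions none,
#: and the weakly modified promoter an intermediate, near-zero level.
PRESETS: dict[str, float] = {
    "her1": 4.0,
    "laco-only": 0.0,
    "abts1b": 0.5,
    "rex1": 4.0,
    "male": 0.0,
}

#: Acquisition geometries available besides the fast per-nucleus default:
#: the full-field still acquisition and the time-lapse raster.
GEOMETRIES: dict[str, tuple[int, int]] = {
    "default": (128, 128),
    "still_640": (640, 640),
    "timelapse_512x256": (512, 256),
}


def preset_params(name: str, seed: int = 0, **overrides) -> SimParams:
    """SimParams for a named experimental-condition preset."""
    key = name.replace("_", "-").lower()
    if key not in PRESETS:
        raise ParameterError(
            f"preset: unknown preset {name!r}; expected one of {sorted(PRESETS)}"
        )
    return SimParams(enrichment=PRESETS[key], seed=seed, **overrides)
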