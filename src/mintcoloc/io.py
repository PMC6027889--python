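"""Disk formats: multi-channel TIFF images, sidecar JSON, manifests, CSV.

Conventions
-----------
* Images are written as (2, rows, cols) unsigned 16-bit TIFF with channel
  0 = YFP (mintbody) and channel 1 = CFP (LacI); intensities above 65535
  saturate on write. A ``--channel-order``/``channel_order`` override
  exists because microscope exports vary.
* Each image has a sidecar JSON (same stem, ``.json``) carrying the
  simulation parameters and ground truth when the image is synthetic, and
  always the cohort metadata (group, nucleus id, frame, timestamp).
* A cohort directory has a ``manifest.csv`` with columns
  path, group, nucleus_id, frame.
* Per-nucleus results are written as CSV with one row per input nucleus,
  including failed ones (status column) — nothing is silently dropped.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import ParameterError
from .images import CFP, YFP, ChannelImage, NucleusImagePair
from .metrics import ColocRecord
from .simulate import GroundTruth, NoiseModel, SimParams, _disk_mask

__all__ = [
    "write_nucleus_pair",
    "read_nucleus_pair",
    "write_cohort",
    "read_cohort",
    "write_mask_tiff",
    "records_to_dataframe",
    "MANIFEST_NAME",
]

MANIFEST_NAME = "manifest.csv"
_CHANNEL_ORDER_DEFAULT = (YFP, CFP)


def _params_to_json(params: SimParams) -> dict:
    d = dataclasses.asdict(params)
    if math.isinf(d["noise_model"]["poisson_gain"]):
        d["noise_model"]["poisson_gain"] = "inf"
    return d


def _params_from_json(d: dict) -> SimParams:
    d = dict(d)
    nm = dict(d.pop("noise_model"))
    if nm["poisson_gain"] == "inf":
        nm["poisson_gain"] = math.inf
    d["image_size"] = tuple(d["image_size"])
    d["nucleus_center"] = tuple(d["nucleus_center"])
    if not isinstance(d["spot_position"], str):
        d["spot_position"] = tuple(d["spot_position"])
    return SimParams(noise_model=NoiseModel(**nm), **d)


def _truth_to_json(truth: GroundTruth, params: SimParams) -> dict:
    # the true mask is a filled disk, so store its parametrization
    return {
        "nucleus_center": list(params.nucleus_center),
        "nucleus_radius": params.nucleus_radius,
        "spot_position": list(truth.spot_position),
        "enrichment_used": truth.enrichment_used,
        "expression_factor": truth.expression_factor,
        "territory_centers": [list(t) for t in truth.territory_centers],
        "spot_positions_per_frame": (
            None if truth.spot_positions_per_frame is None
            else [list(p) for p in truth.spot_positions_per_frame]
        ),
        "timestamps_min": truth.timestamps_min,
    }


def _truth_from_json(d: dict, image_size: tuple[int, int]) -> GroundTruth:
    mask = _disk_mask(image_size, tuple(d["nucleus_center"]), d["nucleus_radius"])
    return GroundTruth(
        true_mask=mask,
        spot_position=tuple(d["spot_position"]),
        enrichment_used=d["enrichment_used"],
        expression_factor=d["expression_factor"],
        territory_centers=[tuple(t) for t in d["territory_centers"]],
        spot_positions_per_frame=(
            None if d.get("spot_positions_per_frame") is None
            else [tuple(p) for p in d["spot_positions_per_frame"]]
        ),
        timestamps_min=d.get("timestamps_min"),
    )


def write_nucleus_pair(
    path: Path | str,
    pair: NucleusImagePair,
    params: Optional[SimParams] = None,
) -> Path:
    """Write one nucleus as 16-bit 2-channel TIFF plus sidecar JSON."""
    path = Path(path)
    stack = np.stack([pair.yfp.pixels, pair.cfp.pixels])
    tifffile.imwrite(path, np.clip(np.round(stack), 0, 65535).astype(np.uint16))
    meta = {
        "nucleus_id": pair.nucleus_id,
        "group": pair.group_label,
        "frame": pair.frame_index,
        "timestamp_min": pair.timestamp_min,
        "channel_order": list(_CHANNEL_ORDER_DEFAULT),
    }
    if params is None:
        params = pair.sim_params
    if params is not None:
        meta["sim_params"] = _params_to_json(params)
    if pair.truth is not None:
        if params is None:
            # no parametrization available: derive the disk from the mask
            meta["ground_truth"] = _truth_bare(pair.truth)
        else:
            meta["ground_truth"] = _truth_to_json(pair.truth, params)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def _truth_bare(truth: GroundTruth) -> dict:
    """Ground-truth JSON when no SimParams are supplied: derive the disk."""
    mask = truth.true_mask
    rr, cc = np.nonzero(mask)
    center = (float(rr.mean()), float(cc.mean()))
    radius = math.sqrt(mask.sum() / math.pi)
    return {
        "nucleus_center": list(center),
        "nucleus_radius": radius,
        "spot_position": list(truth.spot_position),
        "enrichment_used": truth.enrichment_used,
        "expression_factor": truth.expression_factor,
        "territory_centers": [list(t) for t in truth.territory_centers],
        "spot_positions_per_frame": (
            None if truth.spot_positions_per_frame is None
            else [list(p) for p in truth.spot_positions_per_frame]
        ),
        "timestamps_min": truth.timestamps_min,
    }


def read_nucleus_pair(
    path: Path | str,
    channel_order: Sequence[str] = _CHANNEL_ORDER_DEFAULT,
) -> NucleusImagePair:
    """Read a 2-channel TIFF (+ optional sidecar JSON) back into memory."""
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim != 3 or stack.shape[0] != 2:
        raise ParameterError(
            f"{path.name}: expected a (2, rows, cols) TIFF, got shape {stack.shape}"
        )
    order = tuple(channel_order)
    if sorted(order) != sorted(_CHANNEL_ORDER_DEFAULT):
        raise ParameterError("channel_order: must be a permutation of (YFP, CFP)")
    channels = {order[i]: stack[i].astype(float) for i in range(2)}

    meta: dict = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    truth = None
    if "ground_truth" in meta:
        truth = _truth_from_json(meta["ground_truth"], channels[YFP].shape)
    return NucleusImagePair(
        yfp=ChannelImage(channels[YFP], YFP),
        cfp=ChannelImage(channels[CFP], CFP),
        nucleus_id=meta.get("nucleus_id", path.stem),
        group_label=meta.get("group", ""),
        frame_index=int(meta.get("frame", 0)),
        timestamp_min=float(meta.get("timestamp_min", 0.0)),
        truth=truth,
    )


def write_cohort(
    out_dir: Path | str,
    pairs: Sequence[NucleusImagePair],
) -> Path:
    """Write a cohort of nuclei plus ``manifest.csv``; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for pair in pairs:
        name = f"{pair.nucleus_id}_f{pair.frame_index:02d}.tif"
        write_nucleus_pair(out_dir / name, pair)
        rows.append(
            {"path": name, "group": pair.group_label,
             "nucleus_id": pair.nucleus_id, "frame": pair.frame_index}
        )
    manifest = out_dir / MANIFEST_NAME
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(
    in_dir: Path | str,
    channel_order: Sequence[str] = _CHANNEL_ORDER_DEFAULT,
) -> tuple[list[NucleusImagePair], list[dict]]:
    """Read every image of a cohort directory.

    Uses ``manifest.csv`` when present, otherwise globs ``*.tif``. Returns
    the readable pairs plus a list of per-file error records for inputs
    that could not be parsed (the run continues without them).
    """
    in_dir = Path(in_dir)
    manifest = in_dir / MANIFEST_NAME
    if manifest.exists():
        paths = [in_dir / p for p in pd.read_csv(manifest)["path"]]
    else:
        paths = sorted(in_dir.glob("*.tif"))
    if not paths:
        raise ParameterError(f"{in_dir}: no input images found")
    pairs, errors = [], []
    for p in paths:
        try:
            pairs.append(read_nucleus_pair(p, channel_order=channel_order))
        except Exception as exc:  # malformed file: record and continue
            errors.append({"path": str(p), "error": str(exc)})
    return pairs, errors


def write_mask_tiff(path: Path | str, mask: np.ndarray) -> Path:
    """Export a binary mask as single-channel 8-bit TIFF (0/255)."""
    path = Path(path)
    tifffile.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))
    return path


def records_to_dataframe(records: Sequence[ColocRecord]) -> pd.DataFrame:
    """Per-nucleus results table (one row per nucleus, failures included)."""
    rows = []
    for r in records:
        rows.append(
            {
                "nucleus_id": r.nucleus_id,
                "group": r.group_label,
                "frame": r.frame_index,
                "timestamp_min": r.timestamp_min,
                "status": r.status,
                "threshold_used": r.threshold_used,
                "area_px": r.n_mask_px,
                "pcc": r.pcc,
                "n_cfp_spots": len(r.cfp_spots),
                "n_yfp_spots": len(r.yfp_spots),
                "coloc_call": r.coloc_call,
                "min_pair_distance_px": r.min_pair_distance_px,
            }
        )
    return pd.DataFrame(rows)
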