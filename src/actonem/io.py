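"""File containers shared across the package.

Movies travel as multi-page TIFF stacks; dense velocity / order fields as
plain-text CSV grids with a JSON sidecar holding the physical metadata
(pixel size, frame interval, ground truth when generated synthetically).
Writers and readers round-trip bit-exactly for the dtypes they receive.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .flow import VelocityField

__all__ = [
    "write_tiff_movie",
    "read_tiff_movie",
    "write_velocity_field",
    "read_velocity_field",
    "write_json",
    "read_json",
]


def write_tiff_movie(path: str | Path, frames: np.ndarray) -> Path:
    """Write a (T, H, W) stack as a multi-page TIFF (dtype preserved)."""
    path = Path(path)
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValueError("movie must be a (T, H, W) array")
    tifffile.imwrite(path, frames)
    return path


def read_tiff_movie(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(Path(path))
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def write_velocity_field(base: str | Path, field: VelocityField, ground_truth: dict | None = None) -> Path:
    """Write ``<base>.ux.csv``, ``<base>.uy.csv`` and ``<base>.json``.

    The CSV grids hold one row per image row in full float precision; the
    sidecar records pixel size, frame interval and any generator ground
    truth, so an analysis run needs no other context.
    """
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(base.with_suffix(".ux.csv"), field.ux, delimiter=",", fmt="%.17g")
    np.savetxt(base.with_suffix(".uy.csv"), field.uy, delimiter=",", fmt="%.17g")
    meta = {"pixel_size": field.pixel_size, "dt": field.dt, "frame_index": field.frame_index}
    if ground_truth:
        meta["ground_truth"] = ground_truth
    base.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")
    return base


def read_velocity_field(base: str | Path) -> VelocityField:
    base = Path(base)
    meta = json.loads(base.with_suffix(".json").read_text())
    ux = np.loadtxt(base.with_suffix(".ux.csv"), delimiter=",", ndmin=2)
    uy = np.loadtxt(base.with_suffix(".uy.csv"), delimiter=",", ndmin=2)
    return VelocityField(
        ux, uy, pixel_size=meta["pixel_size"], dt=meta["dt"],
        frame_index=meta.get("frame_index", 0),
    )


def write_json(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
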