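"""Read/write image stacks as multi-frame TIFF plus a YAML metadata sidecar.

TIFF tags do not reliably carry pixel size or frame interval, so metadata
lives in ``<stem>.yaml`` next to the TIFF. Reading a stack without the
required metadata raises an explicit error naming the missing field; nothing
is silently defaulted.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
import yaml

from .optics import ImageStack

_REQUIRED = ("pixel_size_nm", "frame_interval_s")


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(".yaml")


def write_stack(stack: ImageStack, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.frames)
    meta = {
        "pixel_size_nm": float(stack.pixel_size_nm),
        "frame_interval_s": float(stack.frame_interval_s),
        "t0_s": float(stack.t0_s),
        "origin_um": [float(v) for v in stack.origin_um],
        "meta": stack.meta,
    }
    with open(sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return path


def read_stack(path) -> ImageStack:
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None, ...]
    sc = sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(
            f"metadata sidecar {sc} not found (required fields: "
            f"{', '.join(_REQUIRED)})")
    with open(sc) as fh:
        meta = yaml.safe_load(fh) or {}
    for key in _REQUIRED:
        if key not in meta:
            raise KeyError(f"stack metadata missing required field '{key}'")
    return ImageStack(
        frames=np.asarray(frames),
        frame_interval_s=float(meta["frame_interval_s"]),
        pixel_size_nm=float(meta["pixel_size_nm"]),
        t0_s=float(meta.get("t0_s", 0.0)),
        origin_um=tuple(meta.get("origin_um", (0.0, 0.0))),
        meta=meta.get("meta", {}) or {},
    )


def as_uint16(stack: ImageStack) -> ImageStack:
    """Quantize frames to 16-bit unsigned counts (camera output format)."""
    frames = np.clip(np.round(stack.frames), 0, np.iinfo(np.uint16).max)
    return ImageStack(frames.astype(np.uint16), stack.frame_interval_s,
                      stack.pixel_size_nm, stack.t0_s, stack.origin_um,
                      dict(stack.meta))
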