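"""Readers and writers for stacks, quads and masks.

The canonical on-disk stack format is a multi-page TIFF with a JSON metadata
sidecar (same basename, ``.json`` suffix) carrying acquisition parameters;
sidecar values override TIFF tags. An HDF5 container (``.h5``/``.hdf5``,
dataset ``frames`` with metadata attributes) is offered for stacks that
exceed memory when memory-mapped workflows are needed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .containers import AcquisitionMeta, PhaseQuad, RawStack
from .errors import StructuralError

__all__ = [
    "read_stack",
    "write_stack",
    "read_phase_quad",
    "write_phase_quad",
    "read_image",
    "write_image",
    "sidecar_path",
]

logger = logging.getLogger(__name__)

_META_FIELDS = (
    "frame_rate", "pixel_pitch", "center_wavelength", "bandwidth_fwhm",
    "full_well", "bit_depth",
)


def sidecar_path(path: Path | str) -> Path:
    return Path(path).with_suffix(".json")


def _meta_from_sidecar(data: dict, shape: tuple[int, int, int]) -> AcquisitionMeta:
    t, y, x = shape
    if "n_frames" in data and int(data["n_frames"]) != t:
        raise StructuralError(
            f"sidecar n_frames={data['n_frames']} disagrees with page count {t}"
        )
    kwargs = {k: data[k] for k in _META_FIELDS if k in data}
    if "frame_rate" not in kwargs:
        logger.warning("no frame_rate in metadata: assuming the 500 fps system default")
    meta = AcquisitionMeta(n_frames=t, height=y, width=x, **kwargs)
    return meta


def write_stack(stack: RawStack, path: Path | str, dtype: str = "float32") -> Path:
    """Write a stack as a multi-page TIFF plus a JSON metadata sidecar.

    ``dtype`` is ``float32`` or ``uint16``; 16-bit output requires the data
    to already be integer-valued within range (it is cast, not rescaled, so
    integer stacks round-trip bit-identically).
    """
    path = Path(path)
    if dtype not in ("float32", "uint16"):
        raise StructuralError("dtype must be 'float32' or 'uint16'")
    tifffile.imwrite(path, stack.frames.astype(dtype), photometric="minisblack")
    meta = asdict(stack.meta)
    sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_stack(
    path: Path | str,
    sidecar: Path | str | None = None,
    meta: AcquisitionMeta | None = None,
) -> RawStack:
    """Read a stack from multi-page TIFF or HDF5.

    Metadata resolution order: explicit ``meta`` argument, then the JSON
    sidecar (auto-detected next to the file when not given), then system
    defaults (500 fps, logged as a warning).
    """
    path = Path(path)
    if not path.exists():
        raise StructuralError(f"no such file: {path}")
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            frames = np.asarray(f["frames"], dtype=float)
            attrs = dict(f["frames"].attrs)
    else:
        frames = np.asarray(tifffile.imread(path), dtype=float)
        attrs = {}
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise StructuralError(f"expected a (T, Y, X) stack, got shape {frames.shape}")
    if meta is None:
        side = Path(sidecar) if sidecar is not None else sidecar_path(path)
        if side.exists():
            attrs.update(json.loads(side.read_text()))
        meta = _meta_from_sidecar(attrs, frames.shape)
    if meta.n_frames != frames.shape[0]:
        raise StructuralError("sidecar n_frames disagrees with page count")
    return RawStack(frames, meta)


def write_stack_h5(stack: RawStack, path: Path | str) -> Path:
    """Write a stack into an HDF5 container (dataset ``frames``)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("frames", data=stack.frames, chunks=True)
        for k, v in asdict(stack.meta).items():
            ds.attrs[k] = v
    return path


def write_phase_quad(quad: PhaseQuad, path: Path | str, dtype: str = "float32") -> Path:
    """Write a quad as a 4-page TIFF, pages ordered I1..I4."""
    path = Path(path)
    tifffile.imwrite(path, quad.frames.astype(dtype), photometric="minisblack")
    if quad.meta is not None:
        sidecar_path(path).write_text(json.dumps(asdict(quad.meta), indent=1, sort_keys=True))
    return path


def read_phase_quad(path: Path | str) -> PhaseQuad:
    """Read a 4-page TIFF as a PhaseQuad, preserving page order I1..I4."""
    path = Path(path)
    if not path.exists():
        raise StructuralError(f"no such file: {path}")
    frames = np.asarray(tifffile.imread(path), dtype=float)
    if frames.ndim != 3 or frames.shape[0] != 4:
        raise StructuralError(f"expected a 4-page TIFF, got shape {frames.shape}")
    meta = None
    side = sidecar_path(path)
    if side.exists():
        data = json.loads(side.read_text())
        # a quad always has 4 pages; the sidecar's n_frames describes the
        # dynamic acquisition setting, so it is carried through, not checked
        kwargs = {k: data[k] for k in _META_FIELDS if k in data}
        meta = AcquisitionMeta(
            n_frames=int(data.get("n_frames", 4)),
            height=frames.shape[1], width=frames.shape[2], **kwargs,
        )
    return PhaseQuad(frames, meta)


def write_image(values: np.ndarray, path: Path | str, dtype: str = "float32") -> Path:
    """Write an image as TIFF: 2-D maps, (N, Y, X) page stacks, or (Y, X, 3) RGB."""
    path = Path(path)
    arr = np.asarray(values).astype(dtype)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.dtype == np.uint8:
        tifffile.imwrite(path, arr, photometric="rgb")
    elif arr.ndim == 3:
        tifffile.imwrite(path, arr, photometric="minisblack")
    else:
        tifffile.imwrite(path, arr)
    return path


def read_image(path: Path | str) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise StructuralError(f"no such file: {path}")
    return np.asarray(tifffile.imread(path))
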