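"""Stack normalization against source flicker and camera response.

Multiplicative light-source fluctuations rescale whole frames; dividing each
frame by its spatial mean and restoring the stack's grand mean removes them
without altering spatial contrast. Camera nonlinearity is handled by an
optional caller-supplied monotone response map (measured -> linearized)
applied pointwise before the gain equalization.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .containers import RawStack
from .errors import DegenerateInputError, StructuralError

__all__ = ["normalize_stack"]


def _apply_response(frames: np.ndarray, response) -> np.ndarray:
    if callable(response):
        out = np.asarray(response(frames), dtype=float)
        if out.shape != frames.shape:
            raise StructuralError("response map changed the stack shape")
        return out
    lut = np.asarray(response, dtype=float)
    if lut.ndim != 2 or lut.shape[1] != 2:
        raise StructuralError("response LUT must be (N, 2): measured, linearized")
    if np.any(np.diff(lut[:, 0]) <= 0):
        raise StructuralError("response LUT abscissa must be strictly increasing")
    return np.interp(frames, lut[:, 0], lut[:, 1])


def normalize_stack(
    stack: RawStack,
    response: Callable[[np.ndarray], np.ndarray] | np.ndarray | None = None,
) -> RawStack:
    """Equalize per-frame spatial means, preserving the global stack mean.

    Each frame is divided by its spatial mean and multiplied by the grand
    mean of all frame means. The operation is idempotent and removes pure
    per-frame gain ("flicker") exactly.

    Parameters
    ----------
    stack : RawStack
        Input time series; every frame must have a positive spatial mean.
    response : callable or (N, 2) array, optional
        Monotone camera-response correction applied pointwise first. A
        two-column LUT is interpolated linearly; a callable is applied as-is.

    Raises
    ------
    DegenerateInputError
        If any frame has a non-positive spatial mean.
    """
    frames = stack.frames
    if response is not None:
        frames = _apply_response(frames, response)
    means = frames.mean(axis=(1, 2))
    if np.any(means <= 0):
        raise DegenerateInputError("every frame must have a positive spatial mean")
    out = frames * (means.mean() / means)[:, None, None]
    return RawStack(out, stack.meta)
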