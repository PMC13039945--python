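"""Conventional FF-OCM amplitude reconstruction from four phase-stepped frames."""

from __future__ import annotations

import numpy as np

from .containers import AmplitudeImage, PhaseQuad

__all__ = ["reconstruct_static"]


def reconstruct_static(quad: PhaseQuad) -> AmplitudeImage:
    """Demodulate the fringe amplitude from a 0/90/180/270-degree quad.

    Computes ``sqrt((I1 - I3)^2 + (I2 - I4)^2)`` pixelwise. For ideal frames
    ``I_k = A + B cos(phi0 + k pi / 2)`` this equals ``2 B`` regardless of
    the incoherent background A and the interferometric phase phi0.
    """
    amplitude = np.hypot(quad.i1 - quad.i3, quad.i2 - quad.i4)
    return AmplitudeImage(amplitude, quad.meta)
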