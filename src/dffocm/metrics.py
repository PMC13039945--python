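"""Resolution and contrast metrics: Fourier ring correlation and CNR.

FRC correlates the spectra of two independent noisy realizations of the same
scene over rings of spatial frequency; the effective resolution is read where
the curve first drops below a threshold (fixed 1/7 by default, half-bit
available). For a single dynamic acquisition the two realizations come from
odd- and even-indexed frame substacks reconstructed independently.

The CNR definition used here is
``|mean(signal) - mean(background)| / sd(background)`` with the sample
standard deviation (denominator N - 1). Other CNR conventions exist (e.g.
pooled-variance denominators); this one is documented rather than presumed
universal.
"""

from __future__ import annotations

import warnings

import numpy as np

from .containers import BandDefinition, FRCCurve, RawStack, RenderConfig
from .dynamic import dynamic_pipeline
from .errors import DegenerateInputError, StructuralError, UndefinedResultError

__all__ = ["frc", "split_stack_frc", "cnr"]

FIXED_THRESHOLD = 1.0 / 7.0


def _half_bit_threshold(n_per_ring: np.ndarray) -> np.ndarray:
    root_n = np.sqrt(np.maximum(n_per_ring, 1))
    return (0.2071 + 1.9102 / root_n) / (1.2071 + 0.9102 / root_n)


def frc(
    image_a: np.ndarray,
    image_b: np.ndarray,
    pixel_pitch: float | None = None,
    ring_width: int = 1,
    criterion: str = "fixed",
) -> FRCCurve:
    """Fourier ring correlation between two equally sized square images.

    Both images are mean-subtracted internally. Rings are defined on the
    integer-rounded radius of the centred discrete spectrum, ``ring_width``
    bins wide. Per ring r,

        FRC(r) = Re( sum F_a conj(F_b) ) / sqrt( sum |F_a|^2 * sum |F_b|^2 ).

    The resolution is ``pixel_pitch / f*`` (same units as ``pixel_pitch``)
    where f* is the first threshold crossing, linearly interpolated between
    rings; with no crossing the estimate is NaN and ``beyond_nyquist`` is set.

    Parameters
    ----------
    criterion : {"fixed", "half-bit"}
        Threshold rule: the constant 1/7, or the half-bit information curve.
    """
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape:
        raise StructuralError("images must share a shape")
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise StructuralError("FRC requires square 2-D images")
    if criterion not in ("fixed", "half-bit"):
        raise ValueError("criterion must be 'fixed' or 'half-bit'")
    n = a.shape[0]

    fa = np.fft.fftshift(np.fft.fft2(a - a.mean()))
    fb = np.fft.fftshift(np.fft.fft2(b - b.mean()))

    idx = np.arange(n) - n // 2
    dist = np.hypot(idx[:, None], idx[None, :])
    ring = np.rint(dist / ring_width).astype(int)
    n_rings = n // 2 // ring_width  # keep rings fully inside the square spectrum
    flat = ring.ravel()

    num = np.bincount(flat, weights=(fa * np.conj(fb)).real.ravel())
    pa = np.bincount(flat, weights=(np.abs(fa) ** 2).ravel())
    pb = np.bincount(flat, weights=(np.abs(fb) ** 2).ravel())
    counts = np.bincount(flat)

    rings = np.arange(1, n_rings + 1)
    denom = np.sqrt(pa[rings] * pb[rings])
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, num[rings] / denom, 0.0)
    ring_freqs = rings * ring_width / n  # cycles/pixel

    if criterion == "fixed":
        threshold = np.full_like(corr, FIXED_THRESHOLD)
    else:
        threshold = _half_bit_threshold(counts[rings].astype(float))

    below = corr < threshold
    if not below.any():
        return FRCCurve(ring_freqs, corr, threshold, counts[rings], pixel_pitch,
                        float("nan"), beyond_nyquist=True)
    k = int(np.argmax(below))  # first ring below threshold
    if k == 0:
        f_star = ring_freqs[0]
    else:
        # linear interpolation of (corr - threshold) between rings k-1 and k
        d0 = corr[k - 1] - threshold[k - 1]
        d1 = corr[k] - threshold[k]
        frac = d0 / (d0 - d1)
        f_star = ring_freqs[k - 1] + frac * (ring_freqs[k] - ring_freqs[k - 1])
    resolution = (pixel_pitch if pixel_pitch is not None else 1.0) / f_star
    return FRCCurve(ring_freqs, corr, threshold, counts[rings], pixel_pitch,
                    float(resolution))


def split_stack_frc(
    stack: RawStack,
    bands: BandDefinition | None = None,
    cfg: RenderConfig | None = None,
    criterion: str = "fixed",
) -> FRCCurve:
    """Single-acquisition FRC from odd/even frame substacks.

    The stack is decimated into odd- and even-indexed substacks, each run
    through the dynamic pipeline independently; the FRC is computed between
    the two band-sum images (sum of the three pre-render band maps). Band
    upper edges are clipped to the substacks' halved Nyquist frequency.
    """
    if stack.n_frames < 8:
        raise DegenerateInputError("split FRC needs at least 8 frames")
    bands = bands or BandDefinition()
    even = stack.substack(slice(0, None, 2))
    odd = stack.substack(slice(1, None, 2))
    sub_bands = bands.clipped_to(even.meta.nyquist)
    if sub_bands != bands:
        warnings.warn(
            f"band edges clipped to the substack Nyquist ({even.meta.nyquist} Hz)",
            stacklevel=2,
        )
    img_a = dynamic_pipeline(even, sub_bands, cfg).band_maps.sum(axis=0)
    img_b = dynamic_pipeline(odd, sub_bands, cfg).band_maps.sum(axis=0)
    return frc(img_a, img_b, pixel_pitch=stack.meta.pixel_pitch, criterion=criterion)


def cnr(
    image: np.ndarray,
    roi_signal: np.ndarray,
    roi_background: np.ndarray,
) -> float:
    """Contrast-to-noise ratio between two regions of interest.

    ``|mean(signal) - mean(background)| / sd(background)``, sample sd. The
    result is invariant to affine intensity rescaling of the whole image.
    """
    image = np.asarray(image, dtype=float)
    sig = np.asarray(roi_signal, dtype=bool)
    bg = np.asarray(roi_background, dtype=bool)
    if sig.shape != image.shape or bg.shape != image.shape:
        raise StructuralError("ROI masks must match the image shape")
    if not sig.any() or not bg.any():
        raise DegenerateInputError("ROI masks must be non-empty")
    if np.any(sig & bg):
        raise DegenerateInputError("signal and background ROIs must be disjoint")
    sd = image[bg].std(ddof=1) if bg.sum() > 1 else 0.0
    if sd == 0:
        raise UndefinedResultError("background sd is zero: CNR undefined")
    return float(abs(image[sig].mean() - image[bg].mean()) / sd)
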