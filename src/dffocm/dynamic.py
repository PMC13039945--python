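"""The dynamic-contrast pipeline.

Per-pixel temporal statistics of a normalized stack: standard deviation,
one-sided fluctuation spectrum (rectangular window, no zero padding, Parseval
scaling), integration into three temporal-frequency bands, log transform with
percentile contrast stretch, RGB assembly, and volumetric stacking with
orthogonal maximum-intensity projections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import (
    BandDefinition,
    DynamicImage,
    FluctuationSpectrumCube,
    RawStack,
    RenderConfig,
)
from .errors import DegenerateInputError, StructuralError
from .preprocess import normalize_stack

__all__ = [
    "temporal_std",
    "pixel_spectrum",
    "integrate_bands",
    "render_rgb",
    "dynamic_pipeline",
    "mean_spectrum",
    "assemble_volume",
    "VolumeRender",
]


def temporal_std(stack: RawStack) -> np.ndarray:
    """Per-pixel sample standard deviation over time (denominator T - 1)."""
    if stack.n_frames < 2:
        raise DegenerateInputError("temporal STD needs at least 2 frames")
    # pre-centre on the first frame: the SD is invariant to a per-pixel
    # temporal constant, and a constant series then yields exactly 0
    return (stack.frames - stack.frames[0]).std(axis=0, ddof=1)


def pixel_spectrum(stack: RawStack, tile_rows: int | None = None) -> FluctuationSpectrumCube:
    """One-sided temporal spectrum of every pixel.

    Rectangular window, no zero padding. Bin k stores the square root of the
    one-sided power, i.e. ``sqrt(2) |X_k| / T`` for interior bins (DC and, for
    even T, the Nyquist bin are not doubled), so that the sum of the squared
    AC bins equals the population temporal variance (Parseval).

    Parameters
    ----------
    stack : RawStack
        Normalized time series with T >= 4.
    tile_rows : int, optional
        Process the image in row tiles of this height. The transform is
        per-pixel, so the result is independent of the tiling; tiles bound
        peak memory for large fields of view.
    """
    t = stack.n_frames
    if t < 4:
        raise DegenerateInputError("pixel spectrum needs at least 4 frames")
    freqs = np.fft.rfftfreq(t, 1.0 / stack.meta.frame_rate)
    # one-sided power weights: double every bin that has a negative-frequency twin
    weights = np.full(freqs.shape, 2.0)
    weights[0] = 1.0
    if t % 2 == 0:
        weights[-1] = 1.0

    def transform(block: np.ndarray) -> np.ndarray:
        spec = np.fft.rfft(block, axis=0) / t
        return np.sqrt(weights[:, None, None] * np.abs(spec) ** 2)

    frames = stack.frames
    if tile_rows is None:
        mags = transform(frames)
    else:
        mags = np.empty((freqs.shape[0],) + frames.shape[1:], dtype=float)
        for y0 in range(0, frames.shape[1], tile_rows):
            mags[:, y0 : y0 + tile_rows] = transform(frames[:, y0 : y0 + tile_rows])
    return FluctuationSpectrumCube(mags, freqs)


def _band_mask(freqs: np.ndarray, lo: float, hi: float, nyquist: float) -> np.ndarray:
    mask = (freqs >= lo) & (freqs < hi) & (freqs > 0)
    if hi >= nyquist * (1 - 1e-12):
        # a band closed at Nyquist collects the Nyquist bin as well
        mask |= np.isclose(freqs, nyquist) & (freqs > 0)
    return mask


def integrate_bands(
    cube: FluctuationSpectrumCube,
    bands: BandDefinition,
    quantity: str = "magnitude",
) -> np.ndarray:
    """Sum the spectral quantity over each band's bins.

    Bin membership is by bin-centre frequency in ``[lo, hi)``; ties at a
    shared edge therefore go to the upper band, and the DC bin is never
    included. Returns a (3, Y, X) array in channel order blue, green, red
    (low, mid, high band).
    """
    if quantity not in ("magnitude", "power"):
        raise ValueError("quantity must be 'magnitude' or 'power'")
    nyquist = float(cube.freqs[-1])
    # the cube's top bin sits at fs/2 only for even T; allow one bin of slack
    df = float(cube.freqs[1] - cube.freqs[0]) if len(cube.freqs) > 1 else 0.0
    bands.validate_nyquist(nyquist + df)
    values = cube.magnitudes if quantity == "magnitude" else cube.power
    out = np.empty((3,) + cube.magnitudes.shape[1:], dtype=float)
    for i, (lo, hi) in enumerate(bands.intervals):
        mask = _band_mask(cube.freqs, lo, hi, nyquist)
        if not mask.any():
            warnings.warn(
                f"band [{lo}, {hi}) Hz contains no spectral bins; returning zeros",
                stacklevel=2,
            )
            out[i] = 0.0
        else:
            out[i] = values[mask].sum(axis=0)
    return out


def _stretch_channel(channel: np.ndarray, cfg: RenderConfig) -> np.ndarray:
    eps = cfg.log_epsilon
    if eps is None:
        eps = max(1e-12 * float(channel.max(initial=0.0)), 1e-30)
    logv = np.log10(channel + eps)
    lo = np.percentile(logv, cfg.zero_low_percent)
    hi = np.percentile(logv, 100.0 - cfg.saturate_high_percent)
    if not hi > lo:
        warnings.warn("constant channel: percentile stretch undefined, rendering zeros",
                      stacklevel=3)
        return np.zeros_like(logv)
    return np.clip((logv - lo) / (hi - lo), 0.0, 1.0)


def render_rgb(band_maps: np.ndarray, cfg: RenderConfig | None = None) -> np.ndarray:
    """Log-transform and percentile-stretch band maps into an RGB image.

    Each channel is mapped ``v -> log10(v + eps)``, clipped at its
    ``zero_low_percent`` and ``100 - saturate_high_percent`` percentiles
    (linear-interpolation percentiles over all pixels) and affinely rescaled
    to [0, 1]: values at or above the upper percentile render as exactly 1,
    at or below the lower as exactly 0. Input order is (blue, green, red)
    band maps; the returned (3, Y, X) array is in display order R, G, B.
    """
    cfg = cfg or RenderConfig()
    maps = np.asarray(band_maps, dtype=float)
    if maps.ndim != 3 or maps.shape[0] != 3:
        raise StructuralError("band_maps must be (3, Y, X) in low, mid, high order")
    if np.any(maps < 0):
        raise StructuralError("band maps must be non-negative")
    blue, green, red = (_stretch_channel(m, cfg) for m in maps)
    return np.stack([red, green, blue])


def dynamic_pipeline(
    stack: RawStack,
    bands: BandDefinition | None = None,
    cfg: RenderConfig | None = None,
    normalize: bool = True,
) -> DynamicImage:
    """Full dynamic-contrast reconstruction of one z-plane.

    Composition normalize -> per-pixel spectrum -> band integration ->
    log/percentile RGB rendering, alongside the temporal-STD map.
    Deterministic for fixed input.
    """
    bands = bands or BandDefinition()
    cfg = cfg or RenderConfig()
    bands.validate_nyquist(stack.meta.nyquist)
    work = normalize_stack(stack) if normalize else stack
    std_map = temporal_std(work)
    cube = pixel_spectrum(work)
    band_maps = integrate_bands(cube, bands, cfg.spectrum_quantity)
    rgb = render_rgb(band_maps, cfg)
    return DynamicImage(rgb, std_map, band_maps, bands, stack.meta)


def mean_spectrum(cube: FluctuationSpectrumCube) -> np.ndarray:
    """Arithmetic mean over all pixel spectra, one value per frequency bin."""
    return cube.magnitudes.mean(axis=(1, 2))


@dataclass(frozen=True)
class VolumeRender:
    """RGB volume with maximum-intensity orthogonal projections."""

    volume: np.ndarray  # (3, Z, Y, X)
    z_step_um: float
    projection_xy: np.ndarray  # (3, Y, X), max over z
    projection_xz: np.ndarray  # (3, Z, X), max over y
    projection_yz: np.ndarray  # (3, Z, Y), max over x


def assemble_volume(images: list[DynamicImage], z_step_um: float) -> VolumeRender:
    """Stack per-plane RGB images into a volume with orthogonal projections.

    Planes must share shape and band definition; plane order is increasing z
    (into the sample).
    """
    if not images:
        raise StructuralError("need at least one image")
    first = images[0]
    for img in images[1:]:
        if img.rgb.shape != first.rgb.shape:
            raise StructuralError("all planes must share the same shape")
        if img.bands != first.bands:
            raise StructuralError("all planes must share the same band definition")
    volume = np.stack([img.rgb for img in images], axis=1)  # (3, Z, Y, X)
    return VolumeRender(
        volume=volume,
        z_step_um=z_step_um,
        projection_xy=volume.max(axis=1),
        projection_xz=volume.max(axis=2),
        projection_yz=volume.max(axis=3),
    )
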