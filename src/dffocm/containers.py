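"""Core data containers for the d-FF-OCM pipeline.

Conventions: image origin is top-left, row-major, x rightward, y downward;
z increases into the sample. Stacks are ``(T, Y, X)`` arrays of non-negative
intensities. Lengths are in nanometres unless a field says otherwise
(stage/reference travel is in micrometres, matching how such stages are
specified).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import DegenerateInputError, ParameterError, StructuralError

__all__ = [
    "AcquisitionMeta",
    "RawStack",
    "PhaseQuad",
    "AmplitudeImage",
    "BandDefinition",
    "FluctuationSpectrumCube",
    "RenderConfig",
    "DynamicImage",
    "FRCCurve",
    "GateCalibration",
]


@dataclass(frozen=True)
class AcquisitionMeta:
    """Camera and illumination parameters of an acquisition.

    Defaults mirror the reference instrument: a high full-well camera
    recording 512-frame stacks at 500 fps with 120 nm sample-plane pixels,
    illuminated by filtered white light (centre ~600 nm, ~200 nm FWHM).

    Parameters
    ----------
    frame_rate : float
        Frames per second (Hz).
    n_frames : int
        Number of frames in a dynamic stack.
    height, width : int
        Image dimensions in pixels.
    pixel_pitch : float
        Sample-plane pixel size in nm.
    center_wavelength : float
        Mean illumination wavelength in nm.
    bandwidth_fwhm : float
        Spectral FWHM in nm; sets the coherence length.
    full_well : float
        Camera full-well capacity in photoelectrons.
    bit_depth : int
        ADC bit depth used when quantizing.
    """

    frame_rate: float = 500.0
    n_frames: int = 512
    height: int = 64
    width: int = 64
    pixel_pitch: float = 120.0
    center_wavelength: float = 600.0
    bandwidth_fwhm: float = 200.0
    full_well: float = 2.0e6
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ParameterError("frame_rate must be > 0")
        if self.n_frames < 2:
            raise ParameterError("n_frames must be >= 2")
        if self.height < 1 or self.width < 1:
            raise ParameterError("image dimensions must be >= 1")
        if self.pixel_pitch <= 0:
            raise ParameterError("pixel_pitch must be > 0")
        if not (0 < self.bandwidth_fwhm < self.center_wavelength):
            raise ParameterError("need 0 < bandwidth_fwhm < center_wavelength")
        if self.full_well <= 0:
            raise ParameterError("full_well must be > 0")
        if self.bit_depth < 1:
            raise ParameterError("bit_depth must be >= 1")

    @property
    def nyquist(self) -> float:
        """Highest temporal frequency representable (Hz)."""
        return self.frame_rate / 2.0

    @property
    def coherence_length_fwhm(self) -> float:
        """FWHM coherence length (nm) of a Gaussian spectrum source.

        l_c = (2 ln 2 / pi) * lambda^2 / delta_lambda.
        """
        return (2.0 * math.log(2.0) / math.pi) * self.center_wavelength**2 / self.bandwidth_fwhm

    def replace(self, **kwargs) -> "AcquisitionMeta":
        return replace(self, **kwargs)


def _check_frames(frames: np.ndarray, ndim: int, name: str) -> np.ndarray:
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != ndim:
        raise StructuralError(f"{name} must be {ndim}-D, got shape {frames.shape}")
    if not np.all(np.isfinite(frames)):
        raise StructuralError(f"{name} contains non-finite values")
    if np.any(frames < 0):
        raise StructuralError(f"{name} contains negative intensities")
    return frames


@dataclass(frozen=True)
class RawStack:
    """A (T, Y, X) intensity time series plus its acquisition metadata."""

    frames: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        frames = _check_frames(self.frames, 3, "frames")
        object.__setattr__(self, "frames", frames)
        t, y, x = frames.shape
        if t != self.meta.n_frames:
            raise StructuralError(
                f"stack has {t} frames but meta.n_frames={self.meta.n_frames}"
            )
        if (y, x) != (self.meta.height, self.meta.width):
            raise StructuralError(
                f"frame shape {(y, x)} disagrees with meta {(self.meta.height, self.meta.width)}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def substack(self, index: slice) -> "RawStack":
        """Frame-subsampled copy with metadata (n_frames, frame_rate) updated.

        Decimating by a step of k divides the effective frame rate by k.
        """
        frames = self.frames[index]
        step = index.step or 1
        if frames.shape[0] < 2:
            raise DegenerateInputError("substack must keep at least 2 frames")
        meta = self.meta.replace(
            n_frames=frames.shape[0], frame_rate=self.meta.frame_rate / step
        )
        return RawStack(frames, meta)


@dataclass(frozen=True)
class PhaseQuad:
    """Four phase-stepped frames I1..I4 at 0/90/180/270 degrees of piezo phase."""

    frames: np.ndarray  # (4, Y, X)
    meta: AcquisitionMeta | None = None

    def __post_init__(self) -> None:
        frames = _check_frames(self.frames, 3, "frames")
        if frames.shape[0] != 4:
            raise StructuralError("PhaseQuad needs exactly 4 frames")
        object.__setattr__(self, "frames", frames)

    @property
    def i1(self) -> np.ndarray:
        return self.frames[0]

    @property
    def i2(self) -> np.ndarray:
        return self.frames[1]

    @property
    def i3(self) -> np.ndarray:
        return self.frames[2]

    @property
    def i4(self) -> np.ndarray:
        return self.frames[3]


@dataclass(frozen=True)
class AmplitudeImage:
    """Demodulated fringe amplitude (2B for ideal four-step data)."""

    values: np.ndarray
    meta: AcquisitionMeta | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise StructuralError("AmplitudeImage must be 2-D")
        if np.any(values < 0):
            raise StructuralError("fringe amplitude cannot be negative")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class BandDefinition:
    """Three ascending temporal-frequency intervals mapped to blue/green/red.

    Intervals are half-open ``[lo, hi)``; a band whose upper edge sits at the
    Nyquist frequency additionally includes the Nyquist bin. Defaults are the
    slow/intermediate/fast subcellular-motion bands 1-3 / 3-100 / 100-250 Hz.
    """

    low: tuple[float, float] = (1.0, 3.0)
    mid: tuple[float, float] = (3.0, 100.0)
    high: tuple[float, float] = (100.0, 250.0)

    def __post_init__(self) -> None:
        bands = (self.low, self.mid, self.high)
        for lo, hi in bands:
            if not (lo < hi):
                raise ParameterError(f"band [{lo}, {hi}) is empty or inverted")
        if bands[0][0] <= 0:
            raise ParameterError("lowest band must start above 0 Hz (DC excluded)")
        for (_, hi_a), (lo_b, _) in zip(bands, bands[1:]):
            if lo_b < hi_a:
                raise ParameterError("bands must be non-overlapping and ascending")

    @property
    def intervals(self) -> tuple[tuple[float, float], ...]:
        """Bands in channel order low -> high (blue, green, red)."""
        return (self.low, self.mid, self.high)

    def validate_nyquist(self, nyquist: float) -> None:
        if self.high[1] > nyquist * (1 + 1e-12):
            raise ParameterError(
                f"top band edge {self.high[1]} Hz exceeds Nyquist {nyquist} Hz"
            )

    def clipped_to(self, nyquist: float) -> "BandDefinition":
        """Copy with upper edges clipped to the Nyquist frequency."""
        def clip(b):
            lo, hi = b
            return (lo, min(hi, nyquist))

        bands = [clip(self.low), clip(self.mid), clip(self.high)]
        # drop-through: an entirely super-Nyquist band becomes a sliver just
        # below Nyquist and will simply collect no bins
        for i, (lo, hi) in enumerate(bands):
            if lo >= hi:
                bands[i] = (nyquist * (1 - 1e-9), nyquist)
        return BandDefinition(*map(tuple, bands))


@dataclass(frozen=True)
class FluctuationSpectrumCube:
    """One-sided per-pixel temporal spectrum.

    ``magnitudes[k]`` is the square root of the one-sided power in bin k, so
    that summing ``magnitudes**2`` over the AC bins reproduces the population
    temporal variance (Parseval). The DC bin is kept at index 0 but is never
    included in band integrals.
    """

    magnitudes: np.ndarray  # (F, Y, X)
    freqs: np.ndarray  # (F,)

    def __post_init__(self) -> None:
        mags = np.asarray(self.magnitudes, dtype=float)
        freqs = np.asarray(self.freqs, dtype=float)
        if mags.ndim != 3:
            raise StructuralError("magnitudes must be (F, Y, X)")
        if freqs.ndim != 1 or freqs.shape[0] != mags.shape[0]:
            raise StructuralError("freqs must match the cube's first axis")
        if np.any(np.diff(freqs) <= 0):
            raise StructuralError("freqs must be strictly increasing")
        if np.any(mags < 0):
            raise StructuralError("spectrum magnitudes must be >= 0")
        object.__setattr__(self, "magnitudes", mags)
        object.__setattr__(self, "freqs", freqs)

    @property
    def power(self) -> np.ndarray:
        return self.magnitudes**2


@dataclass(frozen=True)
class RenderConfig:
    """Log-transform and percentile-stretch parameters for RGB assembly.

    The default stretch saturates the highest 1% of each channel to full
    intensity and floors the lowest 1% to zero.
    """

    saturate_high_percent: float = 1.0
    zero_low_percent: float = 1.0
    log_epsilon: float | None = None  # None -> 1e-12 * channel max, floored at 1e-30
    spectrum_quantity: str = "magnitude"  # or "power"

    def __post_init__(self) -> None:
        for p in (self.saturate_high_percent, self.zero_low_percent):
            if not (0 <= p < 50):
                raise ParameterError("stretch percentages must lie in [0, 50)")
        if self.log_epsilon is not None and self.log_epsilon <= 0:
            raise ParameterError("log_epsilon must be > 0")
        if self.spectrum_quantity not in ("magnitude", "power"):
            raise ParameterError("spectrum_quantity must be 'magnitude' or 'power'")


@dataclass(frozen=True)
class DynamicImage:
    """Output of the dynamic pipeline: RGB rendering plus raw maps.

    ``rgb`` is in display order (red, green, blue); ``band_maps`` keeps the
    band order low, mid, high — i.e. blue, green, red channels, pre-render.
    """

    rgb: np.ndarray  # (3, Y, X) in [0, 1], display order R, G, B
    std_map: np.ndarray  # (Y, X)
    band_maps: np.ndarray  # (3, Y, X) pre-render integrated band values, low->high
    bands: BandDefinition
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        rgb = np.asarray(self.rgb, dtype=float)
        if rgb.ndim != 3 or rgb.shape[0] != 3:
            raise StructuralError("rgb must be (3, Y, X)")
        if np.any(rgb < 0) or np.any(rgb > 1):
            raise StructuralError("rgb values must lie in [0, 1]")
        std_map = np.asarray(self.std_map, dtype=float)
        if std_map.shape != rgb.shape[1:]:
            raise StructuralError("std_map shape disagrees with rgb")
        object.__setattr__(self, "rgb", rgb)
        object.__setattr__(self, "std_map", std_map)
        object.__setattr__(self, "band_maps", np.asarray(self.band_maps, dtype=float))


@dataclass(frozen=True)
class FRCCurve:
    """Fourier ring correlation curve and the resolution read off it.

    ``resolution_nm`` is NaN when the curve never crosses the threshold
    (resolution beyond Nyquist); ``beyond_nyquist`` flags that case.
    """

    ring_freqs: np.ndarray  # cycles/pixel, ascending in (0, 0.5]
    correlation: np.ndarray
    threshold: np.ndarray
    n_per_ring: np.ndarray
    pixel_pitch: float | None
    resolution_nm: float
    beyond_nyquist: bool = False

    @property
    def cutoff_freq(self) -> float:
        """First threshold crossing in cycles/pixel (NaN if none)."""
        if self.beyond_nyquist:
            return float("nan")
        if self.pixel_pitch is None:
            return 1.0 / self.resolution_nm
        return self.pixel_pitch / self.resolution_nm


@dataclass(frozen=True)
class GateCalibration:
    """Result of the reference-arm / sample-stage co-registration sweep."""

    offsets_um: np.ndarray
    contrast: np.ndarray
    optimum_offset_um: float
    displacement_um: float
    slope: float  # um reference travel per um stage travel
    on_boundary: bool = False
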