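"""Synthetic Linnik-interferometer stack generator.

Produces raw interferogram time stacks (and phase-stepped quads) with known
ground truth so every stage of the dynamic pipeline can be tested without
instrument data. The model is scalar, paraxial and single-scatterer-per-pixel:
per pixel and frame,

    I(t) = I_r + I_s + 2 sqrt(I_r I_s) V(Delta(t)) cos(phi0 + 2 pi Delta(t) / lambda)

where ``Delta(t)`` is the double-pass optical path difference (static tilt /
defocus map, plus twice the scatterer axial displacement delta_z(t), plus
twice the residual coherence-gate offset produced by stage travel under
refractive-index mismatch) and ``V`` is the Gaussian fringe-visibility
envelope of a broadband source. Axial scatterer motion enters the phase with
the double-pass factor 4 pi / lambda. No speckle or multiple scattering is
modelled: the emulated source is spatially incoherent precisely to suppress
those.

Detection is shot-noise-limited: photoelectron counts are Poisson-drawn,
clipped at the camera full well and optionally quantized to the ADC bit
depth. Dynamics and noise draw from independent seeded substreams, so the
displacement realization is reproducible with noise toggled on or off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .containers import AcquisitionMeta, PhaseQuad, RawStack
from .errors import ParameterError, StructuralError

__all__ = [
    "DriveComponent",
    "BandNoise",
    "ScattererDynamics",
    "SimulationSpec",
    "coherence_envelope",
    "simulate_stack",
    "simulate_phase_quad",
]


@dataclass(frozen=True)
class DriveComponent:
    """A sinusoidal axial drive applied to one labeled region.

    ``region`` indexes ``ScattererDynamics.region_labels``; pixels in that
    region oscillate axially as ``amplitude * sin(2 pi f t + phase)``.
    """

    region: int
    frequency: float  # Hz
    displacement_amplitude: float  # nm
    phase: float = 0.0  # rad

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ParameterError("drive frequency must be > 0")
        if self.displacement_amplitude < 0:
            raise ParameterError("displacement amplitude must be >= 0")


@dataclass(frozen=True)
class BandNoise:
    """Band-limited Gaussian axial jitter added to a region (or all pixels)."""

    f_lo: float  # Hz
    f_hi: float  # Hz
    rms_displacement: float  # nm
    region: int | None = None  # None -> every pixel

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ParameterError("need 0 < f_lo < f_hi")
        if self.rms_displacement < 0:
            raise ParameterError("rms_displacement must be >= 0")


@dataclass(frozen=True)
class ScattererDynamics:
    """Ground-truth sample: static reflectivity map plus axial motion model.

    ``static_reflectivity`` is the sample-arm intensity per pixel relative to
    the reference-arm intensity, in [0, 1]. ``region_labels`` assigns every
    pixel to an integer region; drive components and band noise address
    regions by label. The same seed yields an identical realization.
    """

    static_reflectivity: np.ndarray  # (Y, X) in [0, 1]
    region_labels: np.ndarray | None = None  # (Y, X) int; default all zeros
    components: tuple[DriveComponent, ...] = ()
    band_noise: tuple[BandNoise, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        refl = np.asarray(self.static_reflectivity, dtype=float)
        if refl.ndim != 2:
            raise StructuralError("static_reflectivity must be 2-D")
        if np.any(refl < 0) or np.any(refl > 1):
            raise ParameterError("static_reflectivity must lie in [0, 1]")
        object.__setattr__(self, "static_reflectivity", refl)
        labels = self.region_labels
        labels = np.zeros(refl.shape, dtype=int) if labels is None else np.asarray(labels, dtype=int)
        if labels.shape != refl.shape:
            raise StructuralError("region_labels shape disagrees with reflectivity")
        object.__setattr__(self, "region_labels", labels)
        object.__setattr__(self, "components", tuple(self.components))
        object.__setattr__(self, "band_noise", tuple(self.band_noise))

    def validate_frequencies(self, frame_rate: float) -> None:
        nyq = frame_rate / 2.0
        for c in self.components:
            if c.frequency >= nyq:
                raise ParameterError(
                    f"drive at {c.frequency} Hz is at/above Nyquist ({nyq} Hz)"
                )
        for b in self.band_noise:
            if b.f_hi > nyq:
                raise ParameterError("band-noise upper edge exceeds Nyquist")

    def displacement(self, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Axial displacement delta_z (nm) as a (T, Y, X) array."""
        labels = self.region_labels
        out = np.zeros((t.shape[0],) + labels.shape, dtype=float)
        for c in self.components:
            mask = labels == c.region
            if not mask.any():
                continue
            series = c.displacement_amplitude * np.sin(
                2.0 * math.pi * c.frequency * t + c.phase
            )
            out[:, mask] += series[:, None]
        if self.band_noise and t.shape[0] >= 4:
            dt = float(t[1] - t[0])
            for b in self.band_noise:
                series = _band_limited_noise(t.shape[0], dt, b.f_lo, b.f_hi, b.rms_displacement, rng)
                if b.region is None:
                    out += series[:, None, None]
                else:
                    mask = labels == b.region
                    if mask.any():
                        out[:, mask] += series[:, None]
        return out


def _band_limited_noise(
    n: int, dt: float, f_lo: float, f_hi: float, rms: float, rng: np.random.Generator
) -> np.ndarray:
    """White Gaussian noise FFT-filtered to [f_lo, f_hi] and rescaled to `rms`."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, dt)
    keep = (freqs >= f_lo) & (freqs <= f_hi)
    spec[~keep] = 0.0
    series = np.fft.irfft(spec, n)
    cur = series.std()
    if cur > 0:
        series *= rms / cur
    return series


@dataclass(frozen=True)
class SimulationSpec:
    """Full parameterization of the synthetic interferometer.

    Parameters
    ----------
    meta : AcquisitionMeta
        Camera/illumination parameters.
    dynamics : ScattererDynamics
        Sample reflectivity and axial motion model.
    reference_intensity : float
        Reference-arm photoelectrons per pixel per frame. The sample-arm
        intensity is ``static_reflectivity * reference_intensity``. A value
        near 10% of full well emulates the attenuated-reference operating
        point of the real instrument.
    coherence_length_fwhm : float or None
        FWHM coherence length (nm); None derives it from the source spectrum
        in ``meta``.
    path_mismatch : array or float
        Static double-pass OPD map (nm), a tilt/defocus surrogate.
    n_sample, n_immersion : float
        Axial refractive indices of sample and immersion medium (>= 1); their
        mismatch displaces the coherence gate from the focal plane as the
        stage moves.
    stage_displacement : float
        Sample-stage travel in um (positive moves the sample toward the
        objective).
    reference_offset : float
        Reference-arm translation in um (positive lengthens the reference
        path, single pass).
    phase_offset : float
        Static interferometric phase phi0 (rad) added to the OPD phase.
    shot_noise, quantize : bool
        Toggle Poisson detection noise and ADC quantization. With
        ``quantize`` the output is in ADU spanning [0, 2**bit_depth - 1];
        otherwise it stays in photoelectrons.
    """

    meta: AcquisitionMeta
    dynamics: ScattererDynamics
    reference_intensity: float = 2.0e5
    coherence_length_fwhm: float | None = None
    path_mismatch: np.ndarray | float = 0.0
    n_sample: float = 1.0
    n_immersion: float = 1.0
    stage_displacement: float = 0.0  # um
    reference_offset: float = 0.0  # um
    phase_offset: float = 0.0  # rad
    shot_noise: bool = False
    quantize: bool = False

    def __post_init__(self) -> None:
        if self.reference_intensity < 0:
            raise ParameterError("reference_intensity must be >= 0")
        if self.n_sample < 1 or self.n_immersion < 1:
            raise ParameterError("refractive indices must be >= 1")
        if self.coherence_length_fwhm is not None and self.coherence_length_fwhm <= 0:
            raise ParameterError("coherence_length_fwhm must be > 0")
        shape = (self.meta.height, self.meta.width)
        if self.dynamics.static_reflectivity.shape != shape:
            raise StructuralError("dynamics maps must match meta height/width")
        pm = np.broadcast_to(np.asarray(self.path_mismatch, dtype=float), shape).copy()
        object.__setattr__(self, "path_mismatch", pm)

    @property
    def coherence_length(self) -> float:
        if self.coherence_length_fwhm is not None:
            return self.coherence_length_fwhm
        return self.meta.coherence_length_fwhm

    @property
    def gate_mismatch_um(self) -> float:
        """Residual single-pass gate offset (um) after reference compensation.

        Stage travel dz under index mismatch requires a single-pass reference
        shift dz * (n_s^2 - n_imm^2) / n_imm to re-centre the coherence gate
        on the focal plane; whatever the applied reference offset does not
        cover remains as gate mismatch.
        """
        required = (
            self.stage_displacement
            * (self.n_sample**2 - self.n_immersion**2)
            / self.n_immersion
        )
        return required - self.reference_offset


def coherence_envelope(path_mismatch, coherence_length_fwhm: float):
    """Gaussian fringe-visibility envelope of a broadband source.

    ``V(Delta) = exp(-4 ln2 Delta^2 / l_c^2)`` with both arguments in nm;
    V(0) = 1 and V is symmetric in the mismatch.
    """
    if coherence_length_fwhm <= 0:
        raise ParameterError("coherence_length_fwhm must be > 0")
    delta = np.asarray(path_mismatch, dtype=float)
    out = np.exp(-4.0 * math.log(2.0) * delta**2 / coherence_length_fwhm**2)
    return out if out.ndim else float(out)


def _rngs(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    dyn_ss, noise_ss = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(dyn_ss), np.random.default_rng(noise_ss)


def _ideal_frames(spec: SimulationSpec, delta_z: np.ndarray, extra_phase: float = 0.0) -> np.ndarray:
    """Noise-free photoelectron frames for a (T, Y, X) displacement field."""
    i_r = spec.reference_intensity
    i_s = spec.dynamics.static_reflectivity * i_r
    # double-pass OPD in nm: static map + 2 dz + 2 * residual gate offset
    delta = (
        spec.path_mismatch[None, :, :]
        + 2.0 * delta_z
        + 2.0 * spec.gate_mismatch_um * 1e3
    )
    vis = coherence_envelope(delta, spec.coherence_length)
    phase = (
        spec.phase_offset
        + extra_phase
        + 2.0 * math.pi * delta / spec.meta.center_wavelength
    )
    return i_r + i_s[None] + 2.0 * np.sqrt(i_r * i_s)[None] * vis * np.cos(phase)


def _detect(frames: np.ndarray, spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.shot_noise:
        frames = rng.poisson(frames).astype(float)
    np.clip(frames, 0.0, spec.meta.full_well, out=frames)
    if spec.quantize:
        levels = 2**spec.meta.bit_depth - 1
        frames = np.rint(frames / spec.meta.full_well * levels)
        np.clip(frames, 0, levels, out=frames)
    return frames


def simulate_stack(spec: SimulationSpec) -> RawStack:
    """Simulate a dynamic acquisition: phase-shifting off, dynamics on.

    Fixed ``dynamics.seed`` yields a bit-identical stack.
    """
    spec.dynamics.validate_frequencies(spec.meta.frame_rate)
    dyn_rng, noise_rng = _rngs(spec.dynamics.seed)
    t = np.arange(spec.meta.n_frames) / spec.meta.frame_rate
    delta_z = spec.dynamics.displacement(t, dyn_rng)
    frames = _ideal_frames(spec, delta_z)
    frames = _detect(frames, spec, noise_rng)
    return RawStack(frames, spec.meta)


def simulate_phase_quad(spec: SimulationSpec) -> PhaseQuad:
    """Simulate four phase-stepped frames with dynamics frozen at t = 0.

    The piezo imposes 0/90/180/270 degrees on top of the static phase.
    """
    spec.dynamics.validate_frequencies(spec.meta.frame_rate)
    dyn_rng, noise_rng = _rngs(spec.dynamics.seed)
    delta_z = spec.dynamics.displacement(np.zeros(1), dyn_rng)
    steps = [0.0, 0.5 * math.pi, math.pi, 1.5 * math.pi]
    frames = np.concatenate(
        [_ideal_frames(spec, delta_z, extra_phase=s) for s in steps], axis=0
    )
    frames = _detect(frames, spec, noise_rng)
    return PhaseQuad(frames, spec.meta)
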