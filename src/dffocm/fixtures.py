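"""Deterministic test fixtures written to disk.

Each preset generates a small synthetic dataset plus a ground-truth manifest
(JSON) used by the test suite and the examples. The same name and seed always
reproduce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .containers import AcquisitionMeta
from .errors import ParameterError
from .gate import predicted_gate_slope
from .io import write_image, write_phase_quad, write_stack
from .simulate import (
    DriveComponent,
    ScattererDynamics,
    SimulationSpec,
    simulate_phase_quad,
    simulate_stack,
)

__all__ = ["make_fixture", "PRESETS", "three_band_spec", "static_sample_spec", "frc_cutoff_pair"]

PRESETS = ("three-band-regions", "static-sample", "gate-mismatch", "frc-cutoff")

# drive frequencies chosen inside the default low/mid/high bands
THREE_BAND_DRIVES = {1: 2.0, 2: 20.0, 3: 200.0}


def _region_labels(shape: tuple[int, int]) -> np.ndarray:
    """Three square regions (labels 1..3) on a static background (0)."""
    labels = np.zeros(shape, dtype=int)
    h, w = shape
    s = min(h, w) // 4
    labels[h // 8 : h // 8 + s, w // 8 : w // 8 + s] = 1
    labels[h // 8 : h // 8 + s, w - w // 8 - s : w - w // 8] = 2
    labels[h - h // 8 - s : h - h // 8, w // 2 - s // 2 : w // 2 - s // 2 + s] = 3
    return labels


def three_band_spec(
    seed: int = 0,
    shape: tuple[int, int] = (64, 64),
    n_frames: int = 512,
    amplitude_nm: float = 10.0,
    shot_noise: bool = False,
) -> SimulationSpec:
    """Three regions driven at 2 / 20 / 200 Hz on a static background.

    The interferometric phase is biased to quadrature (pi/2) so small axial
    drives modulate intensity linearly at the drive frequency.
    """
    meta = AcquisitionMeta(n_frames=n_frames, height=shape[0], width=shape[1])
    labels = _region_labels(shape)
    reflectivity = np.where(labels > 0, 0.5, 0.2)
    comps = tuple(
        DriveComponent(region=r, frequency=f, displacement_amplitude=amplitude_nm)
        for r, f in THREE_BAND_DRIVES.items()
    )
    dyn = ScattererDynamics(reflectivity, labels, comps, seed=seed)
    return SimulationSpec(
        meta=meta, dynamics=dyn, phase_offset=np.pi / 2, shot_noise=shot_noise
    )


def static_sample_spec(
    seed: int = 0, shape: tuple[int, int] = (32, 32), n_frames: int = 128
) -> SimulationSpec:
    """A motionless sample: every pixel's time series is constant (noise off)."""
    meta = AcquisitionMeta(n_frames=n_frames, height=shape[0], width=shape[1])
    rng = np.random.default_rng(seed)
    reflectivity = rng.uniform(0.1, 0.9, shape)
    dyn = ScattererDynamics(reflectivity, seed=seed)
    return SimulationSpec(meta=meta, dynamics=dyn)


def gate_mismatch_spec(seed: int = 0, shape: tuple[int, int] = (16, 16)) -> SimulationSpec:
    """Tissue-like index (1.40) under oil immersion (1.515), uniform sample."""
    meta = AcquisitionMeta(n_frames=8, height=shape[0], width=shape[1])
    dyn = ScattererDynamics(np.full(shape, 0.5), seed=seed)
    return SimulationSpec(meta=meta, dynamics=dyn, n_sample=1.40, n_immersion=1.515)


def frc_cutoff_pair(
    seed: int = 0, n: int = 128, cutoff: float = 0.25, noise_sigma: float = 0.5
) -> tuple[np.ndarray, np.ndarray, float]:
    """Two noisy realizations sharing band-limited structure.

    The common structure is white noise low-pass filtered to a sharp radial
    cutoff (cycles/pixel) in the Fourier plane; each copy gets independent
    white noise. Returns (image_a, image_b, cutoff).
    """
    rng = np.random.default_rng(seed)
    spec = np.fft.fft2(rng.standard_normal((n, n)))
    idx = np.arange(n) - n // 2
    radius = np.fft.ifftshift(np.hypot(idx[:, None], idx[None, :])) / n
    spec[radius > cutoff] = 0.0
    structure = np.fft.ifft2(spec).real
    structure /= structure.std()
    a = structure + noise_sigma * rng.standard_normal((n, n))
    b = structure + noise_sigma * rng.standard_normal((n, n))
    shift = min(a.min(), b.min())
    return a - shift, b - shift, cutoff


def make_fixture(name: str, seed: int, outdir: Path | str) -> dict[str, Path]:
    """Write a named preset to ``outdir``; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if name == "three-band-regions":
        spec = three_band_spec(seed)
        stack = simulate_stack(spec)
        paths = {
            "stack": write_stack(stack, outdir / "three_band_stack.tif"),
            "labels": write_image(spec.dynamics.region_labels, outdir / "three_band_labels.tif", "uint16"),
        }
        manifest = {
            "preset": name,
            "seed": seed,
            "drive_frequencies_hz": {str(r): f for r, f in THREE_BAND_DRIVES.items()},
            "expected_dominant_channel": {"1": "blue", "2": "green", "3": "red"},
            "displacement_amplitude_nm": 10.0,
        }
    elif name == "static-sample":
        spec = static_sample_spec(seed)
        stack = simulate_stack(spec)
        paths = {"stack": write_stack(stack, outdir / "static_stack.tif")}
        manifest = {"preset": name, "seed": seed, "expected_temporal_std": 0.0}
    elif name == "gate-mismatch":
        spec = gate_mismatch_spec(seed)
        displacement = 30.0
        from dataclasses import replace

        quad = simulate_phase_quad(
            replace(spec, stage_displacement=displacement, reference_offset=0.0)
        )
        paths = {"quad": write_phase_quad(quad, outdir / "gate_mismatch_quad.tif")}
        slope = predicted_gate_slope(spec.n_sample, spec.n_immersion)
        manifest = {
            "preset": name,
            "seed": seed,
            "n_sample": spec.n_sample,
            "n_immersion": spec.n_immersion,
            "displacement_um": displacement,
            "predicted_slope_um_per_um": slope,
            "predicted_optimum_offset_um": slope * displacement,
        }
    elif name == "frc-cutoff":
        a, b, cutoff = frc_cutoff_pair(seed)
        paths = {
            "image_a": write_image(a, outdir / "frc_a.tif"),
            "image_b": write_image(b, outdir / "frc_b.tif"),
        }
        manifest = {"preset": name, "seed": seed, "cutoff_cycles_per_pixel": cutoff}
    else:
        raise ParameterError(f"unknown preset {name!r}; known: {PRESETS}")
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    paths["manifest"] = manifest_path
    return paths
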