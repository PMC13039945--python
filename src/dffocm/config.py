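"""Build simulator and pipeline objects from plain dict / YAML configs.

The schema mirrors the dataclasses: a ``meta`` mapping for acquisition
parameters, a ``dynamics`` mapping with rectangular labeled ``regions``,
sinusoidal ``components`` and optional ``band_noise``, and top-level
simulator fields. Validation is delegated to the dataclasses themselves.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .containers import AcquisitionMeta, BandDefinition, RenderConfig
from .errors import ParameterError
from .simulate import BandNoise, DriveComponent, ScattererDynamics, SimulationSpec

__all__ = ["load_config", "spec_from_config", "bands_from_edges", "render_config_from_config"]


def load_config(path: Path | str) -> dict:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ParameterError("config file must contain a mapping")
    return data


def bands_from_edges(edges: list[float] | str) -> BandDefinition:
    """Four ascending edges (e.g. ``"1,3,100,250"``) -> three bands."""
    if isinstance(edges, str):
        edges = [float(e) for e in edges.split(",")]
    if len(edges) != 4:
        raise ParameterError("need exactly 4 band edges (lo, e1, e2, hi)")
    e = [float(x) for x in edges]
    return BandDefinition((e[0], e[1]), (e[1], e[2]), (e[2], e[3]))


def _labels_and_reflectivity(cfg: dict, shape: tuple[int, int]):
    labels = np.zeros(shape, dtype=int)
    reflectivity = np.full(shape, float(cfg.get("background_reflectivity", 0.2)))
    for region in cfg.get("regions", []):
        y0, y1 = int(region["y0"]), int(region["y1"])
        x0, x1 = int(region["x0"]), int(region["x1"])
        labels[y0:y1, x0:x1] = int(region["label"])
        if "reflectivity" in region:
            reflectivity[y0:y1, x0:x1] = float(region["reflectivity"])
    return labels, reflectivity


def spec_from_config(cfg: dict, seed: int | None = None) -> SimulationSpec:
    """Construct a :class:`SimulationSpec` from a config mapping."""
    meta = AcquisitionMeta(**cfg.get("meta", {}))
    dyn_cfg = cfg.get("dynamics", {})
    shape = (meta.height, meta.width)
    labels, reflectivity = _labels_and_reflectivity(dyn_cfg, shape)
    components = tuple(
        DriveComponent(
            region=int(c["region"]),
            frequency=float(c["frequency"]),
            displacement_amplitude=float(c["displacement_amplitude"]),
            phase=float(c.get("phase", 0.0)),
        )
        for c in dyn_cfg.get("components", [])
    )
    band_noise = tuple(
        BandNoise(
            f_lo=float(b["f_lo"]),
            f_hi=float(b["f_hi"]),
            rms_displacement=float(b["rms_displacement"]),
            region=b.get("region"),
        )
        for b in dyn_cfg.get("band_noise", [])
    )
    dynamics = ScattererDynamics(
        static_reflectivity=reflectivity,
        region_labels=labels,
        components=components,
        band_noise=band_noise,
        seed=int(seed if seed is not None else dyn_cfg.get("seed", 0)),
    )
    keys = (
        "reference_intensity", "coherence_length_fwhm", "path_mismatch",
        "n_sample", "n_immersion", "stage_displacement", "reference_offset",
        "phase_offset", "shot_noise", "quantize",
    )
    kwargs = {k: cfg[k] for k in keys if k in cfg}
    return SimulationSpec(meta=meta, dynamics=dynamics, **kwargs)


def render_config_from_config(cfg: dict) -> RenderConfig:
    keys = ("saturate_high_percent", "zero_low_percent", "log_epsilon", "spectrum_quantity")
    return RenderConfig(**{k: cfg[k] for k in keys if k in cfg})
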