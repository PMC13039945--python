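import numpy as np
import pytest

from dffocm import AcquisitionMeta, RawStack, ScattererDynamics, SimulationSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_meta():
    return AcquisitionMeta(n_frames=64, height=8, width=8)


@pytest.fixture
def uniform_spec(small_meta):
    """A uniform motionless sample, noise off."""
    dyn = ScattererDynamics(np.full((8, 8), 0.5))
    return SimulationSpec(meta=small_meta, dynamics=dyn, reference_intensity=1e4)


def make_stack(frames: np.ndarray, frame_rate: float = 500.0) -> RawStack:
    t, y, x = frames.shape
    meta = AcquisitionMeta(frame_rate=frame_rate, n_frames=t, height=y, width=x)
    return RawStack(np.asarray(frames, dtype=float), meta)


@pytest.fixture
def noise_stack(rng):
    """Positive white-noise stack for spectral identities."""
    return make_stack(rng.random((128, 6, 6)) + 1.0)
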