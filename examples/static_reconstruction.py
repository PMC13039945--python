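"""Four-step phase-shifting demodulation of a simulated interferogram quad.

The piezo imposes 0/90/180/270 degree phase steps; the demodulated amplitude
sqrt((I1-I3)^2 + (I2-I4)^2) equals twice the fringe amplitude B and is
independent of the incoherent background and of the static phase.
"""

import numpy as np

from dffocm import (
    AcquisitionMeta,
    ScattererDynamics,
    SimulationSpec,
    reconstruct_static,
    simulate_phase_quad,
)

meta = AcquisitionMeta(n_frames=8, height=32, width=32)
reflectivity = np.full((32, 32), 0.25)  # sample arm at 25% of the reference
spec = SimulationSpec(
    meta=meta,
    dynamics=ScattererDynamics(reflectivity),
    reference_intensity=1.0e5,  # photoelectrons per frame
    phase_offset=0.7,  # arbitrary static phase; the amplitude ignores it
)
quad = simulate_phase_quad(spec)
amplitude = reconstruct_static(quad).values

expected = 2 * 2 * np.sqrt(1.0e5 * 0.25e5)  # 2B with B = 2 sqrt(Ir Is) V, V = 1
print(f"frame means  I1..I4: {[f'{f.mean():.0f}' for f in quad.frames]}")
print(f"demodulated amplitude: {amplitude.mean():.1f} photoelectrons")
print(f"ideal 2B             : {expected:.1f} photoelectrons")
# The demodulated amplitude matches 2B although the four raw frames differ
# strongly -- the incoherent background cancels exactly.
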