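# dffocm

Processing and simulation tools for **dynamic full-field optical coherence
microscopy (d-FF-OCM)** — a label-free imaging modality that turns intrinsic
subcellular motion into fluorescence-like contrast. A Linnik interferometer
with matched high-NA objectives images *en face* planes onto a high
full-well-capacity camera; with the phase-shifting piezo off, metabolic and
cytoskeletal motion modulates the interferometric signal on millisecond
timescales, and the temporal statistics of each pixel become the contrast.

The package is aimed at people building or analysing FF-OCM data: it
implements the full reconstruction chain and a physics-based simulator that
generates raw camera stacks with known ground truth, so every stage can be
validated quantitatively without an instrument.

## What it computes

**Static reconstruction.** From four frames phase-stepped by 0°/90°/180°/270°,
the fringe amplitude is demodulated as

```
A = sqrt((I1 - I3)^2 + (I2 - I4)^2)
```

which equals `2B` for ideal frames `I_k = A0 + B cos(phi0 + k pi/2)`,
independent of the background `A0` and phase `phi0`.

**Dynamic reconstruction.** A T-frame stack (default 512 frames at 500 fps) is
normalized against source flicker, then each pixel's time series is reduced to
(i) its temporal standard deviation and (ii) its one-sided FFT spectrum
(Parseval-scaled: summed AC power equals the temporal variance). The spectrum
is integrated over three bands — low 1–3 Hz, mid 3–100 Hz, high 100–250 Hz —
mapped to blue, green and red; band values are log-transformed, percentile
contrast-stretched (top 1% saturated, bottom 1% zeroed) and assembled into an
RGB image. Per-plane images stack into volumes with orthogonal maximum
projections.

**Metrics.** Fourier ring correlation (fixed-1/7 or half-bit threshold)
between two images or between odd/even-frame half-stack reconstructions gives
a resolution estimate; contrast-to-noise ratio
`|mean(sig) − mean(bg)| / sd(bg)` quantifies contrast.

**Gate tracking.** Under refractive-index mismatch (tissue `n_s` under
immersion oil `n_imm`), moving the stage by Δz requires shifting the reference
arm by `Δz (n_s² − n_imm²)/n_imm` to keep the coherence gate on the focal
plane. The package provides both the closed form and the empirical
sweep-and-maximize-contrast calibration run on the simulator.

**Simulator.** Scalar partial-coherence interference model with a Gaussian
fringe envelope `V(Δ) = exp(−4 ln2 Δ²/l_c²)`, per-region sinusoidal or
band-limited-noise axial dynamics, Poisson shot noise at a 2×10⁶ e⁻ full
well, and ADC quantization — all seeded and bit-reproducible.

## Worked example

`examples/dynamic_contrast.py` simulates three regions oscillating axially at
2, 20 and 200 Hz on a static background and runs the full dynamic pipeline:

```
region  drive    mean R     mean G     mean B    dominant
  1       2.0 Hz  0.144      0.297      1.000     B
  2      20.0 Hz  0.216      1.000      0.184     G
  3     200.0 Hz  1.000      0.257      0.077     R
mean temporal STD, driven regions : 3.86e+04 e-
mean temporal STD, background     : 4.3e+03 e- (9x weaker)
```

Each region's rendered hue is dominated by the channel whose frequency band
contains its drive: slow motion renders blue, intermediate green, fast red —
the mechanism by which d-FF-OCM colour-codes subcellular kinetics. The other
examples demodulate a phase quad (`static_reconstruction.py`), recover a
constructed 0.25 cycles/pixel spectral cutoff by FRC within one ring
(`frc_resolution.py`), and recover the gate-tracking slope −0.221 µm/µm for
tissue under oil against the closed form (`gate_calibration.py`).

A thin CLI mirrors the library:

```
dffocm simulate --config sim.yaml --seed 1 --out stack.tif
dffocm reconstruct-dynamic stack.tif out --bands 1,3,100,250
dffocm frc a.tif b.tif --pixel-pitch 120 --out-csv curve.csv
dffocm calibrate-gate --ns 1.40 --nimm 1.515 --dz 30 --grid -10:0.05:10
```

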