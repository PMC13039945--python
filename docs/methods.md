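# Methods

This note documents the models, numerical choices and limitations behind
`dffocm`. It is the package's own account of its science; every number quoted
here is computed by the test suite or the example scripts.

## Signal model of the simulator

The simulator stands in for a Linnik-type full-field OCM instrument at the
signal level, not the ray-optics level. Per pixel and frame the ideal
photoelectron count is

    I(t) = I_r + I_s + 2 sqrt(I_r I_s) · V(Δ(t)) · cos(φ0 + 2π Δ(t)/λ̄)

- `I_r` — reference-arm intensity (photoelectrons/frame). The default,
  2×10⁵ e⁻, is 10% of the 2×10⁶ e⁻ full well, emulating an attenuated
  reference chosen to operate near the shot-noise-limited optimum.
- `I_s = r · I_r` — sample-arm intensity, with the per-pixel reflectivity
  map `r ∈ [0, 1]` expressed relative to the reference.
- `Δ(t)` — double-pass optical path difference in nm: a static tilt/defocus
  surrogate map, plus `2 δz(t)` from axial scatterer motion (double pass),
  plus twice the residual coherence-gate offset caused by stage travel under
  index mismatch (below).
- `V(Δ) = exp(−4 ln2 · Δ²/l_c²)` — fringe visibility of a Gaussian-spectrum
  source with FWHM coherence length `l_c`. By default `l_c` is derived from
  the source spectrum as `(2 ln2/π) λ̄²/Δλ` ≈ 794 nm for the default
  λ̄ = 600 nm, Δλ = 200 nm (white light above a 490 nm cut-on filter).
- `φ0` — static interferometric phase, a free parameter. Several fixtures
  set it to π/2 (quadrature) so that a small axial displacement modulates
  intensity linearly at the drive frequency; at φ0 = 0 the first-order term
  vanishes and the response is dominated by the second harmonic.

The model is scalar, paraxial and single-scatterer-per-pixel. No speckle,
multiple scattering, NA-dependent PSF or aberrations are modelled — the
emulated source is spatially incoherent precisely to suppress coherent
artifacts, and gate geometry is reduced to the 1-D abstraction described
below. Consequently the simulator validates the *processing chain*, not
image formation in scattering tissue: passing tests demonstrate that the
pipeline extracts the statistics it claims from signals with known spectral
content, not that real tissue produces those signals.

### Scatterer dynamics

`δz(t)` per pixel is the sum of per-region sinusoids (frequency, amplitude
in nm, phase) plus optional band-limited Gaussian jitter (white noise
FFT-masked to `[f_lo, f_hi]` and rescaled to a target RMS, one realization
per region). Real subcellular motion spectra are not characterized here;
sinusoids and band noise are ground-truth stand-ins chosen because their
band membership is exact, which is what the band-integration stage needs to
be tested against. Drive frequencies must lie below Nyquist (frame_rate/2);
violating this is a parameter error, not silent aliasing.

Default fixture amplitudes are 10 nm — about λ̄/60 of phase modulation
(0.2 rad), small enough to stay in the linear regime at quadrature yet far
above the shot-noise floor at the default intensities.

### Detection

With shot noise on, frames are Poisson-drawn at the ideal photoelectron
mean (verified against variance = mean to 5% over 10⁴ frames), clipped at
the full well, and optionally quantized by rounding onto `2^bit_depth − 1`
ADU spanning the full well. One seed feeds two independent substreams
(`numpy` `SeedSequence.spawn`): dynamics and detection noise, so the
displacement realization is reproducible with noise toggled.

## Normalization

Frame-mean gain equalization: each frame is divided by its spatial mean and
multiplied by the grand mean of frame means, removing multiplicative source
flicker exactly while preserving the global stack mean; it is idempotent to
1e−12 relative. How the original instrument normalized (spatial mean,
reference ROI, or photodiode) is not specified anywhere we could follow, so
the simplest contrast-preserving choice was taken; camera nonlinearity is
delegated to an optional caller-supplied monotone response map (default
identity) because a response curve is an instrument property the package
cannot know. One side effect worth knowing: when a large region of the
field fluctuates, mean-normalization couples a small share of that
fluctuation into static pixels (visible as a weak background STD in the
three-band example).

## Spectral analysis

Per-pixel FFT with a rectangular window and no zero padding — bin spacing
is exactly frame_rate/T (0.977 Hz at 500 fps / 512 frames), and a
bin-centred tone is leakage-free, which keeps band membership testable. Bin
k of the stored cube is `sqrt` of the one-sided power (interior bins
doubled; DC and the even-T Nyquist bin not), so summed AC power equals the
population temporal variance (Parseval, asserted at 1e−10 relative). The
temporal STD map uses the sample convention (T−1) and pre-centres each
series on its first frame so a constant series yields exactly zero.

Band integration sums either magnitude (default) or power over bins whose
centre lies in `[lo, hi)`; ties at shared edges go to the upper band, DC is
never included, and a band closed at Nyquist includes the Nyquist bin so
that bands tiling `(0, Nyquist]` conserve total AC power exactly. Whether
the original processing integrated amplitude or power is not stated; both
are provided, with power the mode used for conservation checks. Band edges
default to 1–3 / 3–100 / 100–250 Hz and are configurable — different
reasonable binnings produce similar RGB renderings, so the edges are a
visualization choice, not a measurement.

## Rendering

Per channel: `v → log10(v + ε)` with ε defaulting to 1e−12 of the channel
maximum (floored at 1e−30, so an all-zero channel stays defined), then clip
at the `zero_low_percent` and `100 − saturate_high_percent` linear-interpolation
percentiles and rescale affinely to [0, 1]. With the default 1%/1% stretch
on an all-distinct map, exactly 1% of pixels render at 1.0 and 1% at 0.0. A
constant channel (upper percentile equals lower) renders all-zero with a
warning rather than dividing by zero. The log base and offset are display
conventions; the stretch makes the rendering invariant to overall scale for
values well above ε.

## Fourier ring correlation

Rings are integer-rounded radii of the centred 2-D spectrum, one bin wide
by default; images are mean-subtracted. Threshold criteria: fixed 1/7
(default) or the half-bit curve. The resolution is `pixel_pitch / f*` at
the first threshold crossing, linearly interpolated between rings; a curve
that never crosses reports NaN with a `beyond_nyquist` flag rather than a
fabricated number. The single-acquisition protocol reconstructs odd- and
even-indexed frame substacks independently and correlates their band-sum
maps; decimation halves the effective frame rate, so band edges are clipped
to the substack Nyquist (with a warning). The split strategy and threshold
convention used by any particular instrument group may differ; these
defaults are documented choices, not inferred ones.

## CNR

`|mean(signal) − mean(background)| / sd(background)`, sample sd. This is
one of several CNR conventions in the imaging literature (alternatives pool
both ROIs' variances); it was chosen for its simplicity and scale/offset
invariance and is flagged here because published CNR values are only
comparable within a convention.

## Gate tracking

High-NA focal-shift theory is deliberately reduced to the paraxial 1-D
model: stage travel Δz (sample toward objective) puts the geometric focus
at depth `Δz·n_s/n_imm`, and re-centring the coherence gate there requires
a single-pass reference shift `Δz·(n_s² − n_imm²)/n_imm` — negative (path
shortens) for tissue (n_s ≈ 1.40) under oil (n_imm = 1.515), −0.221 µm/µm.
The empirical calibration mirrors practice: displace the stage 30 µm, sweep
the reference arm, take the contrast argmax. On the simulator the sweep
recovers the closed form within one grid step; the contrast-vs-offset curve
is Gaussian with FWHM `l_c/2` in single-pass offset (~0.4 µm at the default
coherence length), so the default grid step is 0.05 µm. A 1-D linear slope
assumes an axially homogeneous sample index; layered samples would need a
depth-dependent slope, which is out of scope.

## Problem sizes

Defaults throughout target desk-scale validation: 512-frame 64×64 stacks
for the band-encoding checks (the full pipeline runs in well under a second
at this size), 128-frame stacks for volumetric and FRC protocol tests,
16×16 fields for gate-calibration sweeps (201 quads per sweep). All
operations are vectorized per-pixel and scale linearly in pixel count;
`pixel_spectrum` accepts a `tile_rows` argument that bounds peak memory
without changing results.

## Known limitations

- The simulator's dynamics are prescribed spectra, not biology; agreement
  with it says nothing about contrast in real tissue.
- Normalization assumes flicker is spatially uniform; vignetting drift and
  motion are not corrected.
- FRC on band maps inherits any nonlinearity of the log/stretch stage only
  if applied post-render; the implementation correlates pre-render band
  sums to avoid that.
- The gate model ignores NA-dependent focal-shift corrections, dispersion
  and sample heterogeneity.
- 2-phase/5-phase demodulation, HSV or autocorrelation encodings, and SVD
  filtering are intentionally not implemented.
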