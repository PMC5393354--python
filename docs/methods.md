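# Methods

This note documents the models, numerical choices and limitations behind
`epid2dose`: what each pipeline stage assumes, what the synthetic data
emulate, and what passing tests do and do not demonstrate about real
detector data.

## Detector model and pixel-response correction

The panel is modelled as a linear device: each cine frame is

    frame = Poisson(S · c / N) · g(x,y) + d(x,y) + ε,

where `S = Ψ ⊗ K_de` is the ideal glare-blurred signal, `c` the integrated
conversion (ADU per unit fluence over the whole delivery), `N` the number of
frames, `g` a fixed per-pixel gain map (mean 1, default σ = 2 %), `d` a
fixed dark map (default 100 ± 2 ADU) and `ε` Gaussian read noise (default
1 ADU). Defaults put the per-pixel SNR of an integrated unit-amplitude
delivery near 100 (`c = 10⁴`).

Correction follows the standard flood/dark scheme. The stored flood is the
*dark-subtracted per-frame average* of the open-beam stack, so a single raw
frame corrects as `(raw − dark) / flood`. An image integrated over N frames
carries N dark offsets; the reconstruction chain therefore subtracts
`N · dark` (`correct_raw(..., dark_scale=N)`). Omitting this scale is not a
rounding issue — it produced an 8 % MU-nonlinearity in early end-to-end
checks.

Because the flood acquisition itself carries the open-beam profile, flood
normalisation flattens that profile out of every image. The beam-profile
matrix — the reference open-beam map centre-normalised to 1 — multiplies the
corrected image to restore it. The matrix is applied before deconvolution;
the ordering matters only through the slight non-commutation of the
(slowly varying) profile with the glare convolution, which the round-trip
tests bound below 0.1 % in-field.

Dead pixels are flagged when the net flood is non-positive or when a value
deviates from the map median by more than `k_mad` (default 6) robust
standard deviations, using the Gaussian-consistent scaled MAD
(`median_abs_deviation(scale="normal")`). With the raw (unscaled) MAD a
6-MAD cut sits at ≈ 4 σ and falsely flags ~5·10⁻⁵ of clean Gaussian pixels;
the scaled form puts the cut at 6 σ, where false positives are negligible on
a 1024² panel. Flagged pixels are filled after correction with the median of
their live in-grid 8-neighbours (corner/edge pixels use the available
subset).

## Glare kernel K_de

The detector's point response is dominated by optical photon spread in the
Gd₂O₂S scintillator: most light is collected within the pixel of
interaction, with weak millimetre-to-centimetre tails from optical scatter
in the screen and photon scatter in the panel stack. It is modelled
parametrically as a radial density

    K_de(r) = w₀ G(r; σ) + Σᵢ wᵢ exp(−r/sᵢ) / (2π sᵢ²),

a normalised Gaussian core plus exponential tails, discretised at bin
centres and sum-normalised. Packaged per-mode defaults use a 0.34–0.40 mm
core carrying 92–94.5 % of the response and two tails (2.4–3.5 mm and
11–16 mm scales) carrying the rest, slightly broader for higher energies and
slightly narrower for FFF beams; all parameters are user-overridable. The
parametric form preserves the structure the deconvolution stage needs (a
sharp, radially monotone kernel with long tails) without an optical-photon
transport simulation, which is out of scope.

## Pencil-beam kernel K_pb: photon Monte Carlo in water

`K_pb` is the 2D dose deposited in a 2 mm slab at depth d_max (1.5 cm for
6 MV, 2.5 cm for 10 MV, 3.0 cm for 15 MV) by a normally incident photon
pencil beam on a 30 × 30 × 30 cm water box. The transport model:

* free paths sampled from the total attenuation coefficient;
* interaction channel chosen among Compton (Klein–Nishina energy/angle via
  Kahn's rejection method), photoelectric (full local absorption) and pair
  production (local deposition of E − 1.022 MeV plus two isotropic 511 keV
  photons, which are tracked);
* **kerma approximation**: energy transferred to electrons is deposited at
  the interaction point. Secondary electrons at these energies carry
  centimetre ranges, so real kernels are slightly broader; the
  approximation is the standard desk-scale simplification and is applied
  identically to ground-truth generation and reconstruction, so round-trip
  results are unaffected by it;
* photons are killed below 20 keV (deposited locally) or on leaving the box
  (scored as escaped).

Energy bookkeeping (launched = deposited + escaped) closes to floating-point
precision by construction and is asserted to 0.5 %. Per-bin statistical
uncertainty comes from 25-batch statistics; the suite checks the 1/√2
reduction on doubling histories, mirror symmetry within 3 σ, and primary
transmission against exp(−μd).

Cross sections are an authored water table on 40 log-spaced energies
(0.01–20 MeV): Compton from the closed-form Klein–Nishina total cross
section times the electron density of water (3.343·10²³ e/g), photoelectric
as the power law 4.9·(E/10 keV)⁻³·¹ cm²/g, pair production interpolated from
anchor values above threshold. Coherent (Rayleigh) scattering is omitted
(< 5 % above 100 keV); totals are the exact sum of the partials.
Interpolation is log-log for the positive channels, linear for pair. The
resulting μ(1 MeV) = 0.0707 cm⁻¹ and μ(2 MeV) = 0.0493 cm⁻¹ agree with
standard water values (coherent excluded) to 1 %.

Photon spectra are representative bremsstrahlung shapes
`w(E) ∝ E^a (E_max − E)` between 0.25 MeV and the nominal potential, with
`a = 0` for WFF and `a = −0.6` for FFF beams — giving mean energies near
one third of nominal and softer FFF spectra, the qualitative features that
matter for the kernels. They stand in for spectra derived from beam
commissioning data, which are machine-specific.

## Deconvolution and dose conversion

The inverse in `Ψₚ = corrected ⊗⁻¹ K_de` is realised as a Wiener-style
regularised inverse filter,

    Ψ̂ = Î · conj(Ĥ) / (|Ĥ|² + (ε · max|Ĥ|)²),   ε = 10⁻³ by default,

on a reflect-padded grid (pad width = kernel half-width) to keep the long
glare tails from wrapping; the result is cropped back and noise-induced
negatives are clipped to zero with a logged count. For the packaged glare
kernels |Ĥ| stays above ~0.9 everywhere, so noise amplification is ≈ 1.08
and the regularisation bias is ~ε² — noiseless round trips recover fields
to ~10⁻⁴ relative. Note that a *maximum* pixelwise error bound under
Poisson noise at SNR 100 is governed by the counting-noise extreme over
thousands of pixels (≈ 4 % at 3000 pixels), not by the filter; the noisy
round-trip test therefore bounds the interior RMS (< 1.5 %) and 99th
percentile (< 3 %).

Forward conversion `D_w = Ψₚ ⊗ K_pb` uses zero-padded FFT convolution with
the sum-normalised kernel (signal-preserving, geometry-preserving). Kernel
and image pitches must match exactly; mismatches are an error, with an
explicit `resample_kernel` (bilinear + renormalise) for deliberate grid
changes — silent resampling corrupts dosimetry.

Absolute calibration defines `D_EPID` as the mean of the central 5×5-pixel
region of the fully reconstructed relative-dose image of the 100 MU
reference delivery (10×10 cm² field); `F_ABS = 100 cGy / D_EPID`. Taking
D_EPID at the dose stage (after re-convolution) rather than the fluence
stage makes F_ABS independent of the kernel normalisation conventions; the
small CAX ROI suppresses single-pixel noise. For even grids the ROI centres
on pixel n/2, half a pixel off the geometric centre — immaterial on the flat
field centre it reads.

## γ-index

For each evaluated pixel above the low-dose threshold (default 10 % of the
reference maximum),

    γ(r_e) = min over r_r of sqrt(|r_e−r_r|²/δ² + (D_e(r_e)−D_r(r_r))²/Δ²),

with Δ a percentage of the *global* reference maximum. The reference is
bilinearly upsampled (default ×4) and searched over a disk of offsets
starting at 3×DTA. Any candidate beyond radius R contributes γ ≥ R/δ, so
pixels whose current minimum exceeds that guarantee have their search disk
doubled until resolved; the accelerated result is therefore *exactly* the
exhaustive minimum over the upsampled grid (asserted to 10⁻⁶ against a
brute-force oracle), at the cost of extra passes only where γ is large.
Discretisation of the DTA term is bounded by the upsampled grid spacing.
Grids of different pitch are compared on the evaluated grid, aligned on
their geometric centres. Above-threshold pixels whose entire search region
lies outside the reference extent are excluded from the evaluated mask and
logged. Swapping evaluated and reference roles is exactly symmetric in the
dose term only without upsampling; with upsampling the candidate sets
differ, which is why the symmetry test runs at `interp_factor=1`.

## Synthetic study conditions

The simulator emulates a 20.48 cm square panel; the physical device is
1024 × 1024 at 0.2 mm and ≤ 50 fps, and tests/examples run the same
geometry at desk scale, 128 px at 1.6 mm (256 px at 0.8 mm for the
fluence-recovery study), with 2·10⁵ Monte-Carlo histories per kernel —
sizes at which the full study runs in seconds while leaving every algorithm
path identical to full scale. Fields are binary apertures (squares,
rectangles, circles, simple MLC polygons rasterised at pixel centres)
blurred with a 3 mm Gaussian penumbra and shaped by the open-beam profile:
WFF `1 + 0.04 u² e^(1−u²)` with `u = r/80 mm` (≈ 4 % horns at 8 cm), FFF
`exp(−(r/198 mm)²)` (≈ 15 % lower at 8 cm). These packaged shapes stand in
for water-scan data. Synthetic plans sum random jittered-rectangle segments
with random weights, emulating a time-integrated dynamic delivery.

Because the forward model shares `K_de` with the inverse model
(linear-shift-invariant detector), round-trip results verify *pipeline
correctness*, not detector-model fidelity: passing tests show the chain
inverts its own physics exactly and degrades gracefully under realistic
noise. They do not validate the glare parametrisation against a real
scintillator stack, ghosting/lag, MU-rate dependence, beam-spectrum drift,
or support-arm backscatter — none of which are modelled. A
`mismatch_kernel`-style robustness probe can be built by blurring with one
glare kernel and deconvolving with another.

Output factors are CAX dose ratios, and the pencil-beam kernel makes CAX
dose field-size dependent through lateral scatter; the generator therefore
calibrates segment amplitudes so the *ground-truth dose ratios* equal the
requested output factors, which is what "generated output factor" means
throughout.

## Numerical conventions and degenerate inputs

* Grid centre: index (n−1)/2 per axis; for even n the midpoint between the
  two central pixels. All mm positions are relative to this centre.
* Kernels have odd dimensions with the peak in the central bin and are
  sum-normalised to 10⁻⁶.
* Raw binary stacks are uint16 little-endian, row-major, frames
  concatenated, with a JSON sidecar (rows/cols/pitch/frames/energy/fps);
  truncated files report the index of the incomplete frame.
* Cine stacks may be averaged or integrated; integration is the default
  input to dose conversion since dose tracks total collected signal.
* Empty stacks, geometry/pitch mismatches, non-positive flood at live
  pixels, self-intersecting polygons and fields exceeding the grid are
  rejected with specific errors rather than coerced.
* Rasterisation samples pixel centres; an aperture edge falling exactly on
  a column of pixel centres resolves outward by strict containment, a
  half-pixel convention visible only in area-counting tests.

## Known limitations

Electron transport (kerma approximation) narrows K_pb tails relative to
reality; the glare kernel is parametric, not derived from optical
simulation; spectra are generic bremsstrahlung shapes; the 2 cm build-up
slab above the panel is not modelled geometrically (its effect is absorbed
into the kernels); gantry rotation is represented only as a time-integrated
composite; and no attempt is made to model panel ghosting, temperature
drift or dose-rate dependence.
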