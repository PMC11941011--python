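# Methods

## Model and assumptions

The pipeline treats a consumer camera as an unknown smooth map from scene
reflectance to RGB and inverts it in two coupled regressions fitted on a
24-patch colour checker.

**Colorimetry.** Tristimulus values use the reflective-sample convention
`X = k ∫₄₀₀⁷⁰⁰ S(λ)R(λ)x̄(λ)dλ` (similarly Y, Z) with
`k = 100/∫ S ȳ dλ`, so a perfect reflector has Y = 100 under any
illuminant. Integration is by the trapezoid rule on the native grid
(second-order accurate; halving the step changes XYZ of smooth spectra by
well under 0.1 %). The working grid is 380–780 nm at 1 nm: the tristimulus
window is 400–700 nm, but the 780 nm display band needs the wider axis.
The colour-matching functions are the multi-lobe piecewise-Gaussian
analytic fit to the CIE 1931 2° observer (accurate to about a percent of
the tabulated values and exactly self-consistent within the package, which
is what the synthetic experiments require); D65 is interpolated from a
packaged 10 nm table and renormalised to 100 at 560 nm. Lab conversion and
CIEDE2000 use the standard formulations with kL = kC = kH = 1; the Lab
white point defaults to D65, matching the sRGB rendering used everywhere
else. Out-of-gamut RGB values are never clipped inside the calibration
maths — the regressions need unclipped residuals — only at export.

**Variable matrix.** Each linear RGB triple is expanded into the complete
monomial basis of degree ≤ 3 plus a constant dark term, 20 terms in the
fixed order `[R,G,B | R²,G²,B²,RG,GB,RB | R³,G³,B³,R²G,R²B,G²R,G²B,B²R,
B²G,RGB | 1]`. The cap at third order avoids over-correction: with 24
training patches, higher orders would interpolate the noise. Lower orders
are nested prefixes, so in-sample residuals are provably non-increasing in
the order (a property the tests exercise).

**Fits.** The correction matrix `C = XYZ_ref · pinv(V)` and transformation
matrix `M = Score · pinv(V)` are both Moore–Penrose least squares; singular
values below 1e-10 of the largest are truncated, and a near-rank-deficient
design triggers a warning but not a failure. `Score` is the matrix of
six mean-centred PCA component scores of the measured patch reflectances.
`V` is built directly from linear camera RGB for both fits; the corrected
XYZ of the first fit feeds diagnostics only. Reconstruction is
`R = mean + componentsᵀ·(M·v)`, evaluated vectorised over whole images with
a tested contract that it equals the per-pixel loop.

A structural limitation worth stating: six spectral scores cannot be
recovered exactly through a three-channel bottleneck. Even noiselessly, the
polynomial regression leaves a small residual (~3×10⁻³ mean RMSE on the
packaged chart projected onto its own six-component span). Exactness holds
only when the data-generating scores are themselves functions of the
variable-matrix terms; the test suite checks parameter recovery to 1e-6 in
that regime and bounds the residual in the general one. In practice the
residual is far below the quality bounds the pipeline is expected to meet
(mean patch RMSE ≤ 0.056, ≥ 23/24 patches < 0.1).

## Narrow-band synthesis

Band images are unit-weight Gaussian filters applied along the spectral
axis: centres 415 and 540 nm at FWHM 30 nm (commercial narrow-band filters
are of this order) plus 600/700/780 nm support bands at FWHM 20 nm. A FWHM
at or below the grid step degenerates to the nearest spectral slice. The
display mapping follows the NBI pseudo-colour convention: 415 nm → blue and
green channels, 540 nm and the longer bands → red. Compositing is linear in
the band weights before the final clip to [0, 1] (positive homogeneity is a
tested invariant).

**Band-weight calibration.** Two checkpoints are exposed, mirroring the two
stages a hardware-matching workflow uses. The *linear colour-matching
stage* fits an unconstrained 3×n_bands least-squares map from band
responses to target XYZ. The *FSA stage* optimises non-negative band
weights (plus a scalar gain on bands intersecting the 450–540 nm window,
where most light is absorbed) to minimise mean CIEDE2000 against the target
colours, using fast simulated annealing: per-coordinate Cauchy–Lorentz
proposals with scale γ·T, Metropolis acceptance, temperature multiplied by
0.95 every 20 iterations from T₀ = 1, default 2000 iterations, γ₀ = 0.2, all
driven by an explicit seed (default 20240714). At T = 0 the algorithm
reduces to greedy descent, and the best-so-far trace is non-increasing by
construction. The heavy Cauchy tails give occasional long jumps early on,
which is what lets 2000 iterations suffice for the low-dimensional weight
problems here. When several long-wavelength bands feed the same display
channel their individual weights are only weakly identifiable — the
objective has a flat valley — so weight-recovery guarantees are stated up
to that degeneracy; the achieved colour difference is the meaningful
quantity.

## Synthetic data: what it emulates and what it does not

The generator provides every pipeline input with known ground truth.

- **Reference chart**: 24 smooth analytic reflectances (sigmoid cut-on
  edges and Gaussian bands, six flat neutral steps from 0.92 down to
  0.031) emulating the classic checker's patch set. They reproduce the
  low effective dimensionality of natural-surface reflectance — six
  principal components capture 99.98 % of the chart's variance — but they
  are synthetic stand-ins, not measured chart data.
- **Virtual camera**: Gaussian sensitivities peaking at 600/550/460 nm,
  gamma 1.05, dark level 0.002, seeded Gaussian readout noise (default
  σ = 0.002). The mild nonlinearity and offset are deliberate: they give the
  third-order variable matrix real work. Integration uses the same
  400–700 nm window and luminance normalisation as the tristimulus
  convention, so CMF sensitivities reproduce XYZ/100 exactly (a test
  anchor).
- **Virtual spectrometer**: additive seeded Gaussian noise, clipped at
  zero.
- **Lesion phantom**: a circular lesion on skin. Background reflectance is
  a smooth skin-like curve attenuated Beer–Lambert-style by a synthetic
  hemoglobin absorbance (bands at 415, 542, 577 nm); the lesion disk is
  additionally attenuated by a melanin-like exponential decay
  (normalised at 400 nm, 150 nm length scale). Defaults: 32×32 px, radius
  8, melanin OD 0.8, hemoglobin OD 0.3, 1 % log-normal texture. These are
  parametric stand-ins chosen to exercise the 415/540 nm contrast
  mechanism, not literature extinction spectra.

Consequently, passing tests demonstrate that the pipeline recovers spectra
and enhances chromophore contrast *when the scene obeys the smooth,
low-rank, Beer–Lambert world of the generator*. They do not demonstrate
robustness to real-skin spectral diversity, specular highlights,
demosaicing artefacts, illumination non-uniformity or camera PSF — all of
which are out of scope.

## Numerical choices

- Pseudoinverse truncation at 1e-10·σ_max; warning (not error) on near
  rank deficiency.
- Reflectance overshoot: spectra tolerate values up to 1.2 (flagged);
  reconstructed cubes live in [−0.1, 1.3] in memory and clip to [0, 1] on
  export. Negative reflectance is a contract violation everywhere.
- Saturated pixels (any channel ≥ 0.999) are flagged in a mask and still
  converted.
- Evaluation window for spectral RMSE defaults to 400–700 nm (configurable
  to the full grid): reconstruction is least constrained in the long-red
  tail where the camera carries little information.
- PSNR of identical images is reported capped at 100 dB. Entropy uses a
  256-bin histogram over [0, 1]; the "entropy difference" diagnostic is the
  relative difference of the two images' entropies in percent. SSIM is
  reported on the luminance channel for colour images (per-channel values
  also available).
- sRGB decoding happens exactly once, at image ingest; all calibration
  maths is in linear light.

## Problem sizes

The packaged experiments run at desk scale: 24 calibration patches on a
401-point grid, 32×32 lesion phantoms (16×16 in the pipeline smoke tests)
and 2000 annealing iterations. The full test suite completes in a few
seconds; the acceptance script in well under a minute.

## Known limitations

- The analytic CMF fit deviates from the tabulated observer by up to about
  1 %; absolute XYZ values are therefore approximate, while every
  comparison inside the package (calibration, ΔE00 bounds, synthesis) is
  self-consistent.
- Calibration transfers only to images from the same camera model under
  the same illuminant; no chromatic adaptation transform is applied.
- The pipeline does not model RAW/Bayer decoding, multi-illuminant scenes
  or fluorescence beyond tolerating mild reflectance overshoot.
- Weight recovery in the FSA stage is identifiable only up to the display
  mapping's degeneracies (see above).
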