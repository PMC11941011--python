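# savehsi

**RGB-to-hyperspectral reconstruction and narrow-band enhanced imaging for
skin-lesion visualization.**

Narrow-band imaging (NBI) illuminates tissue at 415 nm (the hemoglobin
absorption peak) and 540 nm to make superficial vasculature and pigmented
structure stand out — but it requires dedicated endoscopic hardware. This
package implements a spectrum-aided vision enhancement pipeline that gets a
comparable rendering from an ordinary RGB photograph: it calibrates the
camera against a 24-patch colour checker, reconstructs a full reflectance
spectrum for every pixel, extracts narrow spectral bands from the
reconstructed cube and composites them into an NBI-style pseudo-colour
image. It is aimed at researchers in biomedical imaging who want white-light
photographs of skin lesions re-rendered with chromophore contrast enhanced.

## Method

Camera RGB triples are expanded into a third-order polynomial *variable
matrix* `V` (all monomials of degree ≤ 3 in R, G, B plus a constant dark
term — 20 terms), which absorbs sensor nonlinearity and channel cross-talk.
Two least-squares fits against colour-checker measurements define the
calibration:

- **Colour correction**  `C = [XYZ_ref] · pinv(V)`, mapping `V` to
  spectrometer-referenced tristimulus values, so corrected colours satisfy
  `[XYZ_corr] = C · V`. Tristimulus values follow the CIE 1931 convention
  `X = k ∫ S(λ) R(λ) x̄(λ) dλ` over 400–700 nm with
  `k = 100 / ∫ S(λ) ȳ(λ) dλ`.
- **Spectral reconstruction**  The patch reflectance spectra are decomposed
  by PCA into six principal components (on the packaged reference chart
  these capture > 99.6 % of the variance); the *transformation matrix*
  `M = [Score] · pinv(V)` maps `V` to the six component scores, so any pixel's
  reflectance is `R(λ) = mean(λ) + Σ_k (M·v)_k · PC_k(λ)`.

The enhanced image samples the reconstructed cube with Gaussian band
filters at 415 and 540 nm (plus 600/700/780 nm support bands), maps 415 nm
to the display blue and green channels and the longer bands to display red.
Band weights can be calibrated to a target colour response by minimising
the mean CIEDE2000 colour difference with **fast simulated annealing**,
whose proposals follow the Cauchy–Lorentz visiting distribution
`f(x; x₀, γ) = γ / (π[(x−x₀)² + γ²])` with scale shrinking as the
temperature cools.

Because no public camera/spectrometer data ship with the package, a
synthetic module provides every input with known ground truth: a smooth
24-patch reference chart, a virtual camera (Gaussian sensitivities, gamma
1.05, dark level 0.002, seeded readout noise), a virtual spectrometer, and
circular lesion phantoms whose melanin/hemoglobin-like absorption makes the
415/540 nm bands diagnostic.

## Worked example

```python
import savehsi as sh

grid = sh.SpectralGrid()                       # 380-780 nm at 1 nm
checker = sh.make_reference_checker(grid)
cam = sh.default_virtual_camera(grid, noise_sigma=0.002, seed=20240714)
rgb = sh.simulate_camera_capture(checker, cam)
measured = sh.simulate_spectrometer(checker.reflectances, 0.002, seed=20240715)

model = sh.SpectralCalibration(rgb, measured, grid)
results = model.fit(order=3, n_components=6)
print(results.summary())
```

```
Spectral calibration results
============================================================
polynomial order:            3   (terms: 20)
principal components:        6
explained variance:          99.98 %
mean patch spectral RMSE:    0.0064
mean dE00 (reconstruction):  0.469
mean dE00 (corrected XYZ):   0.464
mean dE00 (pre-correction):  9.307
```

The summary reads: the six components explain 99.98 % of the chart's
spectral variance; reconstructed patch spectra deviate from the
spectrometer measurements by 0.0064 RMS reflectance on average; rendering
the reconstructed spectra back to colour lands within 0.47 ΔE00 of the
reference colours (a difference well below visibility), versus 9.3 ΔE00
for the uncorrected camera colours.

Converting an image and compositing the enhanced rendering:

```python
cube, mask = sh.make_lesion_scene(sh.LesionSceneParams(grid=grid))
camera_img = sh.simulate_camera_capture(cube, cam).clip(0, 1)
recon = results.convert_image(camera_img)       # H x W x 401 reflectance
enhanced = sh.synthesize_save_image(recon)      # 415/540 nm pseudo-colour
```

The same stages are available from the shell:

```sh
save simulate checker --out sim/
save calibrate --checker-spectra sim/checker_spectra.csv \
               --checker-rgb sim/checker_rgb.csv --out bundle.json
save convert --bundle bundle.json --in photo.png --out cube.npz
save render  --in cube.npz --out enhanced.png
save evaluate --ref reference.png --test enhanced.png --out report.json
save run --out demo/          # full synthetic pipeline + manifest
```

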