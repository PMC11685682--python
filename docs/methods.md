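# Methods

## Model overview

`nbisim` treats simulated narrow-band imaging as three composed maps:

1. a *camera correction* from decoded camera XYZ to spectrometer-referenced
   XYZ, fit on a 24-patch color checker;
2. a *spectral reconstruction* from corrected XYZ to a reflectance spectrum,
   via a PCA basis of the checker reflectances and a polynomial score
   regression;
3. a *re-illumination* of the reconstructed spectrum under a sum-of-
   Lorentzians narrow-band illuminant, rendered back to sRGB.

The assumptions worth making explicit:

* **Reflectances are low-dimensional.** A tristimulus measurement carries
  three degrees of freedom, so step 2 can only invert color→spectrum on a
  spectral family of (at most) three effective dimensions. Natural surface
  reflectances are famously close to such a family; narrow spectral
  features uncorrelated with color (metameric-black components) are
  invisible to the reconstruction and are not recovered.
* **The scene is reflective and the illuminant known.** All spectra are
  reflectances in [0, 1]; the calibration illuminant enters the
  spectrometer-side XYZ and is assumed stable between calibration and use.
* **Colorimetry is D65-referenced.** Rendered outputs are sRGB, so Lab
  conversions and ΔE values use the D65 white point throughout.

## Colorimetry

* Wavelength grid: 380–780 nm at 1 nm (401 samples). Integration is a plain
  Riemann sum at the grid step; at 1 nm resolution a trapezoid correction
  changes nothing at the tolerances used anywhere in the package.
* Observer: CIE 1931 2° color-matching functions in the multi-lobe
  piecewise-Gaussian analytic form (sums of two-sided Gaussians per curve),
  clipped at zero. This reproduces the tabulated observer to about 1 % of
  peak — ample here, because the correction matrix C absorbs any fixed
  observer bias and no result depends on absolute CMF tabulation accuracy.
* sRGB: IEC 61966-2-1 piecewise transfer (not a bare 2.2 power). The
  RGB↔XYZ matrices are derived at import from the primaries' chromaticity
  coordinates rather than hardcoded rounded tables, so the anchors hold at
  machine precision: linear white ↔ the D65 white point, and the luminance
  row sums to exactly 1. XYZ is kept on a 0–100 scale (Y = luminance
  percent).
* Luminance-ratio normalization: `k = 100 / Σ E(λ) ȳ(λ)` inside
  spectrum→XYZ, so a perfect reflector has Y = 100 under any non-degenerate
  illuminant, and rendered colors are invariant to the illuminant's overall
  amplitude (relied on by the optimizer: one band amplitude is pinned).
* ΔE: DE76 (Euclidean), DE94 (graphic-arts weights, asymmetric in its
  reference argument) and CIEDE2000 with kL = kC = kH = 1 including the
  G-correction, piecewise mean-hue rules and rotation term. The test suite
  checks CIEDE2000 against an independently coded scalar transcription and
  against scikit-image.

## Camera correction

* Variable expansion: the 11 second-order monomials
  {1, X, Y, Z, XY, XZ, YZ, X², Y², Z², XYZ}, evaluated on XYZ/100 to keep
  the design matrix well conditioned. 24 patches over-determine the 11
  coefficients per output channel. The expansion is configurable; the
  constant term is mandatory and first.
* Solver: ordinary least squares via `numpy.linalg.lstsq` after an explicit
  rank check that names the deficient situation (too few patches, or
  degenerate patch geometry). No regularization: calibration inputs are
  24 designed, well-spread colors, not noisy field data.
* Calibration error is reported as RMSE pooled over all 3n scalar XYZ
  components on the 0–100 scale.

## Spectral reconstruction

* PCA: mean-centered, via SVD of the 24×401 data matrix. Components are
  sign-fixed deterministically (largest-|coefficient| entry positive).
  Identical spectra raise a degenerate-variance error rather than returning
  an arbitrary basis. Default n_pc = 12 (configurable 1–23): 24 smooth
  patches leave 12 components essentially noise-free while keeping the
  score regression over-determined.
* Score regression reuses the same 11-term expansion by default. Rows of M
  are independent least-squares problems; rank deficiency reports which
  expansion columns are redundant on the given design.
* Reconstruction adds the mean spectrum back and clips to [0, 1] at output
  only — fitting and diagnostics see raw residuals. Cube conversion is
  vectorized over pixels but follows the scalar path operation-for-
  operation (verified to 1e−12 in the tests).
* Cubes serialize to a compressed `.npz` archive with keys
  `wavelengths_nm` and `reflectance`, axis order (row, column, wavelength).

## Narrow-band model and optimization

* Bands are peak-normalized Lorentzian lines `A γ²/((λ−λ0)²+γ²)` (HWHM γ).
  Default centers {415, 480, 540, 600, 700, 780} nm: the two hemoglobin
  peaks, a blue-green shoulder, and red-end bands for the brown tones seen
  in clinical NBI.
* Default rendering amplitudes (1, 0.02, 0.50, 0.40, 0.02, 0.01): the
  415 nm band dominates, 540 nm carries half its weight, and the 600 nm
  band pulls the illuminant's white point back toward neutral. Clinical NBI
  processors white-balance their display similarly — mucosa shows only a
  mild cast while vessels go dark. This balance also preserves the
  perceptual contrast gain: under a strongly green illuminant both regions
  of a scene acquire high chroma, where CIEDE2000's chroma compression
  (S_C = 1 + 0.045·C̄) shrinks differences.
* Optimizer: `scipy.optimize.dual_annealing` — generalized simulated
  annealing with a Cauchy-Lorentz visiting distribution — with the standard
  GSA controls (visit 2.62, accept −5.0, initial temperature 5230),
  default 250 iterations. The annealer alone plateaus on this landscape, so
  the fit runs a deterministic multi-start (default 5 restarts, per-restart
  seeds derived from the config seed) and finishes each restart with a
  bounded L-BFGS-B polish (ftol 1e−15). Identical seeds and inputs give
  bitwise-identical results and traces. Search bounds: centers within
  ±15 nm of the reference model (intersected with the grid), γ ∈ [1, 60] nm,
  amplitudes ∈ [0, 1] with the first pinned (scale invariance makes the
  amplitude space identifiable only up to a common factor).
* Objective: arithmetic mean of the 24 patch-wise CIEDE2000 values between
  patches rendered under the candidate illuminant and the reference NBI
  patch colors, paired by patch id.

## Synthetic fixtures

The generators emulate the *conditions* of a checker-based calibration, not
any specific measured data:

* **Checker reflectances**: patches 1–18 are random non-negative
  combinations of a constant term plus (by default) two Gaussian bumps
  *shared across patches* — centers drawn once per seed from a blue
  (435–460 nm) and a red-orange (595–630 nm) window, widths σ ∈ [25, 65] nm
  — rescaled into [0, 1]. The shared basis gives a three-dimensional
  spectral family, matching the three degrees of freedom a tristimulus
  pipeline can resolve; this is the property that makes the planted
  end-to-end chain solvable (zero noise → every patch reconstructs below
  0.02 RMSE; measured ≈ 0.003 max over seeds). Per-patch independent bumps
  would instead inject metameric-black variation that *no* color-based
  reconstruction can recover — a fundamental identifiability limit, not an
  implementation one. Patches 19–24 are the flat gray ramp
  {0.03, 0.09, 0.19, 0.36, 0.59, 0.90}.
* **WLI illuminant**: constant pedestal plus blue (450 nm) and amber
  (600 nm) Gaussian lobes whose three weights are solved exactly so a
  perfect reflector lands on the D65 white point — a color-balanced lamp.
  Flat grays therefore render as neutral sRGB, and decoding the camera RGB
  recovers the spectrometer-side XYZ up to 8-bit quantization without a
  separate white-balance stage.
* **Lesion phantom**: a flat 0.60 background and a lesion obtained by
  multiplying it with Lorentzian absorption dips at 415 nm (depth 0.60,
  γ 15 nm) and 540 nm (depth 0.45, γ 20 nm) — hemoglobin-like. Rendered
  under the WLI illuminant as a disk on a square.
* Everything is a pure function of the fixture config; a fixed seed
  reproduces all outputs bitwise.

What passing tests on these fixtures do **not** show: performance on real
tissue (textured, specular, noisy, with reflectances outside any
three-dimensional family), robustness to camera noise and demosaicing, or
agreement with any specific commercial NBI processor's proprietary
rendering.

## Numerical choices and degenerate inputs

* Tolerances: planted-matrix recoveries are exact to 1e−8 (pure least
  squares); colorimetric anchors (Y = 100, L\* = 100, sRGB round trip) to
  1e−9…1e−6; the CIEDE2000 cross-check to 1e−4 over 1000 random pairs.
* Degenerate inputs raise typed errors before any computation: zero
  illuminant (against ȳ), identical spectra in PCA, rank-deficient
  regression designs (with the offending columns named), mismatched grids,
  unpaired patch ids, out-of-bounds optimizer inits.
* 8-bit quantization bounds the calibration floor: decoded camera XYZ sits
  within ≈0.1 RMSE (0–100 scale) of the spectrum-side XYZ on the synthetic
  checker; the correction matrix cannot (and need not) do better.

## Known limitations

* Spectra reconstructed from color carry only three independent degrees of
  freedom; narrow spectral features (e.g. the exact shape of hemoglobin
  dips) are recovered only to the extent they project onto the checker's
  PCA basis. The phantom's contrast enhancement is correspondingly milder
  than what a true spectral measurement would give.
* The contrast-gain behaviour depends on the rendering band model's white
  balance: narrowing the 415 nm band increases lesion contrast only down
  to roughly its default width (15 nm); below that a peak-normalized
  Lorentzian loses total power faster than it concentrates on the dip, and
  contrast falls again.
* The DE94 implementation follows the asymmetric reference-first
  convention; only DE76 and DE2000 are symmetric.
* No spatial processing: denoising, vessel enhancement or texture synthesis
  are out of scope; the conversion is purely per-pixel.
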