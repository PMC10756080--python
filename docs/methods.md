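# Methods

## Discretization of the phasor transform

The continuous phasor integrals are discretized as rectangle-rule sums over
the channel *centres* of a uniform spectral axis, with the mid-bin convention
`λₖ = λ_min + (k + ½)Δ`, `Δ = (λ_max − λ_min)/n`. Mid-bin centres were chosen
over left-edge centres for two reasons: (a) full-period symmetry then maps a
spectrally flat spectrum *exactly* to the phasor origin, and (b) on the
default 423–723 nm / 30-channel axis the 498 nm calibration point (phase 90°)
is an exact channel centre. The continuous phase↔wavelength calibration
`λ = λ_min + (λ_max − λ_min)·ϴ/360` is identical under either convention.

Against a 10,000-point trapezoid quadrature of the continuous integrals, the
30-channel mid-bin sums agree to better than 10⁻³ in G and S for smooth
spectra with FWHM ≥ 2 channel widths (measured discretization error for a
Gaussian(530 nm, 60 nm) is ≈ 2·10⁻⁶); narrow near-delta lines agree to
machine precision in phase because a symmetric line's mass centres on its
peak.

## Polar convention

Phase is `atan2(S, G)` in degrees, counterclockwise from (1, 0), wrapped to
[0, 360); modulation is `√(G²+S²)`. A sometimes-quoted shorthand defining
modulation as S/G and phase as arctan(G/S) is internally inconsistent (it
produces unbounded "modulations"); the standard polar form used here is the
one consistent with modulation values bounded by 1 and with the
phase-encodes-centre-of-mass, modulation-encodes-width reading. A phasor at
the exact origin (within 10⁻¹² — e.g. a flat spectrum) has no defined phase;
such pixels are flagged invalid rather than silently assigned 0°.

## Intensity threshold

Pixels whose total counts fall below a threshold are excluded everywhere.
The default ("auto") threshold is 3× the modal total count of the stack: the
histogram mode estimates the blank slide/background level when background is
present in the field of view (the phantom generator always includes a dark
margin for this reason). For fields with no background the mode sits on
tissue and auto-thresholding over-masks — programmatic analyses of
full-coverage fields should pass an explicit threshold (0 keeps every
nonzero pixel). Zero-total pixels are always invalid.

## Denoising

Phasor-space denoising median-filters the G and S planes independently
(default 3×3 kernel, 1 pass; no published kernel size exists, so this is the
smallest symmetric choice). The median is taken over valid neighbours only,
so masked pixels neither contribute nor spread; intensity and mask are
untouched. A constant region's phasor is provably unmoved; on Poisson-noised
phantoms the filter strictly shrinks each material's cluster spread.

## Cursors, palette, stitching

Cursor membership is boundary-inclusive (ties break toward selection).
Pseudocolour phase maps sweep HSV hue red→violet over an explicit phase
range, default 45°–180° (≈ 460–573 nm); the range is configuration, not a
constant, because no single published anchor pair is self-consistent.
Tile mosaics average overlapping pixels channel-wise (no feathering):
since the transform normalises out any constant intensity scale, the blend
rule only affects seam pixels whose neighbours disagree by noise. Stitching
precedes transformation, matching whole-slide phasor practice; on non-overlap
pixels stitch-then-transform equals transform-then-mosaic exactly.

## Unmixing

Two-component unmixing orthogonally projects a phasor onto the segment
joining the pure fingerprints; three-component unmixing solves the 2×2
barycentric system, flagging and renormalizing out-of-triangle points.
**Fractions are emitted-intensity fractions** (shares of detected photons),
not molar fractions; conversion would need per-component brightness, which
label-free tissue data cannot supply. k-means centroids (scikit-learn, fixed
seed 0, 10 restarts) are sorted by phase angle for reproducible ordering.
The packaged fingerprint CSV is computed from the synthetic default spectra
below and is a configurable stand-in, not a measured reference.

## Group statistics

Per-sample phase/modulation centres of mass are computed on unbinned
per-pixel values with equal weights — f(x) is read as the pixel-count
distribution — matching the bin-width→0 limit of the binned histogram CM;
intensity weighting is available behind a flag. Group comparison is the
pooled-variance two-sided t-test (`scipy.stats.ttest_ind` defaults),
significance threshold α = 0.01; zero-pooled-variance degenerate inputs
return p = 1 (equal means) or p = 0 (unequal), logged. Confidence ellipses
are covariance-eigendecomposition ellipses about the group mean with
Mahalanobis membership (distance ≤ k), so orientation follows the
phase–modulation covariance; degenerate (collinear) clouds floor the minor
axis at 10⁻⁹ with a warning. For a bivariate normal the k = 1, 2, 3 ellipses
cover 39.3 / 86.5 / 98.9 % (1 − e^(−k²/2)); the familiar 68.5 / 95.5 / 99.7 %
labels are the 1-D σ coverages and reports print both conventions.

## Synthetic phantoms

The generator emulates the acquisition this pipeline targets: 8-bit lambda
stacks on the 423–723 nm / 30-channel axis, optional rectangular tiling with
5 % overlap, and a 5-nevus + 5-melanoma cohort layout. Pixel spectra are
linear mixtures of (skewed-)Gaussian component emission models — collagen
I–IV, elastin, NADH, FAD, melanin stand-ins ordered blue→red (peaks 455,
465, 470, 480, 495, 462, 535, 615 nm) — scaled to a photon budget, Poisson
noised, and quantized. These spectra are *plausible stand-ins*, configurable
per run; they are not measured emission spectra. Defaults chosen once:
1000 expected counts per tissue pixel (the level at which two-component
fraction recovery is specified to 0.02), a flat 20-count slide background,
256×256 phantom and 128×128 cohort images (desk-scale; full 1024×1024 tiles
are configuration away), and per-sample mixture-weight jitter SD 0.03 for
between-patient variability. Nevus lesions weight NADH/elastin/collagen-like
(blue) components, melanoma lesions FAD/melanin-like (red) ones, so injected
group separation follows the components' chemistry. The generator records
each sample's ground-truth lesion phasor (phase/modulation of the noiseless
lesion mixture), which downstream cohort analysis must recover.

What the phantoms do **not** model: optics (PSF, scattering, depth
attenuation), detector gain/offset, fixation effects, spatial texture within
regions, and any melanoma component redder than the configured melanin
stand-in. Passing tests therefore demonstrate correctness of the transform,
segmentation, unmixing and statistics under the stated noise model — not
clinical performance on real tissue.

## Numerical notes and limitations

* Validity propagates: invalid pixels are excluded from histograms, CMs,
  centroids and cursors; they are never zero-filled into statistics.
* Tile cutting searches for the tile edge length whose rounded-overlap grid
  covers the image exactly, and raises when none exists.
* The t-test assumes approximately normal per-sample CMs (reasonable — each
  CM averages thousands of pixels) and equal variances; with n = 5 per group
  the test is exactly calibrated only under those assumptions.
* Phase wrap-around: samples whose lesion phase straddles 0°/360° would bias
  a naive circular-mean-free CM; the default axis and component library keep
  all phases well inside (0°, 270°), so no circular statistics are used.
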