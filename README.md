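# hsiphasor

Spectral-phasor analysis of label-free hyperspectral fluorescence images of
melanocytic skin lesions.

Melanocytic lesions (benign nevi vs invasive melanoma) differ in the
biochemical makeup of their autofluorescent molecules — collagens, elastin,
NADH, FAD and melanin. Imaged on a confocal microscope as a *lambda stack*
(a full emission spectrum at every pixel, here 423–723 nm in 30 channels of
10 nm), these differences show up without any stain. `hsiphasor` turns such
stacks into quantitative group comparisons for dermatopathology research:
which endogenous fluorophores dominate a lesion, and whether the spectral
summary statistics separate diagnosis groups.

## The method

Each pixel's spectrum I(λ) is reduced to its first-harmonic Fourier pair —
the **spectral phasor**:

    G = Σₖ Iₖ cos(2πn xₖ) / Σₖ Iₖ,   S = Σₖ Iₖ sin(2πn xₖ) / Σₖ Iₖ,
    xₖ = (λₖ − λ_min)/(λ_max − λ_min),   n = 1

Every nonnegative spectrum lands inside the unit disc. In polar form, the
**phase** ϴ = atan2(S, G) encodes the spectral centre of mass (redder
emission → larger phase; on the default axis 90° ↔ 498 nm, 180° ↔ 573 nm)
and the **modulation** ϱ = √(G²+S²) encodes the spectral width (narrower →
closer to 1). Three Fourier properties drive the analysis:

* **uniqueness** — each spectral shape has one phasor, so similar pixels
  cluster;
* **linear combination** — a two-emitter mixture lies on the segment joining
  the pure emitters' phasors, its position giving the emitted-intensity
  fraction (`unmix_two`, `unmix_three`);
* **reciprocity** — a geometric *cursor* in phasor space selects the image
  pixels whose spectra fall there, and an image ROI yields its own secondary
  phasor (`select_by_cursor`, `phasor_of_roi`).

Per sample, the lesion-ROI phase and modulation histograms are summarised by
their centres of mass CM = Σ f(x)·x / Σ f(x); groups are compared with
pooled-variance two-sample t-tests (α = 0.01) and visualised as
modulation-vs-phase scatters with covariance-aligned confidence ellipses.

Because no patient hyperspectral data are publicly deposited, the package
ships a synthetic tissue-phantom generator (`hsiphasor.synthetic`) producing
8-bit lambda stacks — Poisson-noised linear mixtures of configurable
fluorophore emission spectra arranged in dermis / epidermis / lesion-nest
geometry, optionally tiled with 5 % overlap — together with ground-truth
labels and phasor coordinates, so every pipeline stage is testable end to end.

## Worked example

```python
import numpy as np
from hsiphasor import make_cohort, phasor_transform, cohort_compare

samples = make_cohort(seed=1, size=(128, 128))   # 5 nevi + 5 melanomas
res = cohort_compare(
    [(s.label, phasor_transform(s.stack), s.lesion_mask) for s in samples]
)
print(res.summary())
```

prints

```
Cohort phase/modulation comparison
==================================================
melanoma     n=5   phase CM  154.89 ± 5.67 deg   modulation CM 0.295 ± 0.009
nevus        n=5   phase CM   61.46 ± 0.48 deg   modulation CM 0.810 ± 0.002
--------------------------------------------------
phase        t =   36.742   p = 3.30e-10 *  (alpha = 0.01)
modulation   t = -120.684   p = 2.48e-14 *  (alpha = 0.01)
--------------------------------------------------
ellipse levels k=1,2,3: 2-D coverage 39.3/86.5/98.9% (1-D sigma labels 68.5/95.5/99.7%)
```

The synthetic melanoma lesions are built red-shifted (FAD/melanin-weighted
mixtures) relative to the nevi (NADH/elastin/collagen-weighted): their phase
CM is higher and, because the mixed red components broaden the spectrum,
their modulation CM is lower. Both group differences are significant far
below the α = 0.01 threshold; the `*` marks significance. The recovered CMs
agree with each sample's injected ground truth (`s.true_phase_cm`,
`s.true_modulation_cm`) to within the photon-noise floor.

The same pipeline runs from the shell on TIFF stacks:

```
hsiphasor simulate --preset cohort-5x5 --seed 1 --out-dir sim
hsiphasor compare --manifest sim/cohort.csv --out-dir report
```

writing `per_sample.csv`, `group_stats.json`, an ellipse figure, and the
exact run configuration into `report/`.

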