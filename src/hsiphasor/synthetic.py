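"""Synthetic tissue phantoms: lambda stacks with known spectral ground truth.

Each phantom pixel's expected spectrum is a linear mixture of endogenous
fluorophore emission spectra (collagen I-IV, elastin, NADH, FAD, melanin
stand-ins), scaled to a photon budget, Poisson-noised and quantized to the
acquisition bit depth.  Regions follow a tissue-like layout — a dark slide
margin, an epidermis band, a dermis background, and circular melanocytic
nests — and the generator records the ground-truth label image and the exact
phasor coordinates of each region's mixture spectrum, so every pipeline stage
can be scored against truth.

The component spectra are *configurable stand-ins* with a plausible blue
(collagen/NADH-like) to red (melanin-like) emission ordering; they are not
measured spectra of the actual molecules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from skimage.draw import disk

from .io import TileSet
from .spectral import (
    HSIStack,
    PhasorField,
    SpectralAxis,
    phase_modulation,
    phasor_transform,
)

__all__ = [
    "ComponentSpec",
    "PhantomConfig",
    "TissuePhantom",
    "CohortSampleData",
    "make_spectrum",
    "make_tissue_phantom",
    "make_cohort",
    "DEFAULT_COMPONENTS",
    "NEVUS_LESION_MIXTURE",
    "MELANOMA_LESION_MIXTURE",
    "component_fingerprints",
]

#: emission window within which component peaks must fall (nm)
EMISSION_WINDOW = (380.0, 780.0)


@dataclass(frozen=True)
class ComponentSpec:
    """A pure fluorophore emission model: (skewed) Gaussian peak in nm.

    ``skew`` in (-1, 1) widens the red (positive) or blue (negative) flank of
    the Gaussian while keeping the peak wavelength fixed; ``brightness`` is
    the relative integrated emission.
    """

    name: str
    peak: float
    fwhm: float
    skew: float = 0.0
    brightness: float = 1.0

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError(f"{self.name}: FWHM must be > 0, got {self.fwhm}")
        lo, hi = EMISSION_WINDOW
        if not lo <= self.peak <= hi:
            raise ValueError(
                f"{self.name}: peak {self.peak} nm outside emission window {EMISSION_WINDOW}"
            )
        if not -1 < self.skew < 1:
            raise ValueError("skew must lie in (-1, 1)")


# Stand-in emission models, blue collagen-like through red melanin-like.
DEFAULT_COMPONENTS: Dict[str, ComponentSpec] = {
    c.name: c
    for c in (
        ComponentSpec("collagen_I", peak=455.0, fwhm=70.0),
        ComponentSpec("collagen_II", peak=465.0, fwhm=75.0),
        ComponentSpec("collagen_III", peak=470.0, fwhm=75.0),
        ComponentSpec("collagen_IV", peak=480.0, fwhm=80.0),
        ComponentSpec("elastin", peak=495.0, fwhm=80.0),
        ComponentSpec("nadh", peak=462.0, fwhm=70.0),
        ComponentSpec("fad", peak=535.0, fwhm=75.0),
        ComponentSpec("melanin", peak=615.0, fwhm=120.0, skew=0.25),
    )
}

#: benign lesions lean on NADH / elastin / collagen-like (blue) emission
NEVUS_LESION_MIXTURE = {"nadh": 0.40, "elastin": 0.30, "collagen_I": 0.30}
#: melanoma nests lean on FAD / melanin-like (red) emission
MELANOMA_LESION_MIXTURE = {"fad": 0.45, "melanin": 0.40, "nadh": 0.15}

DERMIS_MIXTURE = {"collagen_I": 0.45, "collagen_III": 0.25, "elastin": 0.30}
EPIDERMIS_MIXTURE = {"nadh": 0.50, "fad": 0.30, "collagen_IV": 0.20}


def make_spectrum(spec: ComponentSpec, axis: SpectralAxis) -> np.ndarray:
    """Sample a component's emission model on the axis channel centres.

    The vector is nonnegative and scaled so that a fully in-window emission
    sums to the component's relative brightness; emission falling outside the
    axis window is truncated (an entirely out-of-window component yields a
    near-zero vector, masked downstream).
    """
    sigma = spec.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    lam = axis.channel_centers
    d = lam - spec.peak
    side_sigma = np.where(d >= 0, sigma * (1 + spec.skew), sigma * (1 - spec.skew))
    vec = np.exp(-0.5 * (d / side_sigma) ** 2)
    # full-line integral of the two-sided Gaussian, in channel-width units
    full = np.sqrt(np.pi / 2.0) * sigma * ((1 + spec.skew) + (1 - spec.skew))
    return vec * (axis.channel_width / full) * spec.brightness


def mixture_spectrum(
    weights: Dict[str, float],
    axis: SpectralAxis,
    components: Dict[str, ComponentSpec] = DEFAULT_COMPONENTS,
) -> np.ndarray:
    """Intensity spectrum of a weighted component mixture (sum ~1, minus any
    emission truncated at the axis window)."""
    _check_weights(weights)
    vec = np.zeros(axis.n_channels)
    for name, w in weights.items():
        base = replace(components[name], brightness=1.0)
        vec += w * make_spectrum(base, axis)
    return vec


def _check_weights(weights: Dict[str, float]) -> None:
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mixture weights must sum to 1, got {total}")
    if any(w < 0 for w in weights.values()):
        raise ValueError("mixture weights must be nonnegative")


@dataclass
class PhantomConfig:
    """Full description of a tissue phantom; the seed determines the output.

    Geometry emulates a whole-slide acquisition: 8-bit lambda stacks on the
    423-723 nm / 30-channel axis, optionally cut into a tile grid with 5%
    overlap.  ``mean_counts`` is the expected total photon count per tissue
    pixel; the slide margin emits ``background_counts`` (spectrally flat).
    """

    size: Tuple[int, int] = (256, 256)
    axis: SpectralAxis = field(default_factory=SpectralAxis.default)
    region_mixtures: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {
            "dermis": dict(DERMIS_MIXTURE),
            "epidermis": dict(EPIDERMIS_MIXTURE),
            "lesion": dict(NEVUS_LESION_MIXTURE),
        }
    )
    components: Dict[str, ComponentSpec] = field(
        default_factory=lambda: dict(DEFAULT_COMPONENTS)
    )
    mean_counts: float = 1000.0
    background_counts: float = 20.0
    bit_depth: int = 8
    margin_fraction: float = 0.08
    epidermis_fraction: float = 0.15
    n_nests: int = 3
    nest_radius_fraction: float = 0.12
    tile_grid: Tuple[int, int] = (1, 1)
    overlap_fraction: float = 0.05
    poisson_noise: bool = True
    seed: int = 0

    #: label codes in the ground-truth label image
    LABELS = {"background": 0, "dermis": 1, "epidermis": 2, "lesion": 3}


@dataclass
class TissuePhantom:
    """Generator output: stack, ground-truth labels and region phasors."""

    stack: HSIStack
    labels: np.ndarray
    region_phasors: Dict[str, Tuple[float, float]]
    region_spectra: Dict[str, np.ndarray]
    config: PhantomConfig
    tiles: Optional[TileSet] = None

    def lesion_mask(self) -> np.ndarray:
        return self.labels == PhantomConfig.LABELS["lesion"]


def _label_image(config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = config.size
    labels = np.full((h, w), PhantomConfig.LABELS["dermis"], dtype=np.uint8)
    m = int(round(config.margin_fraction * min(h, w)))
    if m > 0:
        labels[:m, :] = 0
        labels[-m:, :] = 0
        labels[:, :m] = 0
        labels[:, -m:] = 0
    eh = int(round(config.epidermis_fraction * h))
    if eh > 0:
        band = labels[m : m + eh, m : w - m] if m > 0 else labels[:eh, :]
        band[...] = PhantomConfig.LABELS["epidermis"]
    r = max(2, int(round(config.nest_radius_fraction * min(h, w))))
    lo_y, hi_y = m + eh + r + 1, h - m - r - 1
    lo_x, hi_x = m + r + 1, w - m - r - 1
    for _ in range(config.n_nests):
        cy = int(rng.integers(lo_y, max(lo_y + 1, hi_y)))
        cx = int(rng.integers(lo_x, max(lo_x + 1, hi_x)))
        rr, cc = disk((cy, cx), r, shape=labels.shape)
        labels[rr, cc] = PhantomConfig.LABELS["lesion"]
    return labels


def _tile_length(extent: int, n: int, overlap: float) -> int:
    """Tile edge length whose overlapped grid covers ``extent`` exactly."""
    if n == 1:
        return extent
    for t in range(int(np.ceil(extent / n)), extent + 1):
        o = int(round(t * overlap))
        if t + (n - 1) * (t - o) == extent:
            return t
    raise ValueError(
        f"no tile size covers extent {extent} with {n} tiles at overlap {overlap}"
    )


def _cut_tiles(stack: HSIStack, grid: Tuple[int, int], overlap: float) -> TileSet:
    """Cut a mosaic into an overlapping rectangular tile grid."""
    rows, cols = grid
    H, W, _ = stack.intensities.shape
    th = _tile_length(H, rows, overlap)
    tw = _tile_length(W, cols, overlap)
    oh, ow = int(round(th * overlap)), int(round(tw * overlap))
    tiles, positions = [], []
    for r in range(rows):
        for c in range(cols):
            y = r * (th - oh)
            x = c * (tw - ow)
            tiles.append(
                HSIStack(
                    intensities=stack.intensities[y : y + th, x : x + tw].copy(),
                    axis=stack.axis,
                    bit_depth=stack.bit_depth,
                )
            )
            positions.append((r, c))
    return TileSet(tiles=tiles, grid_positions=positions, overlap_fraction=overlap)


def make_tissue_phantom(config: PhantomConfig) -> TissuePhantom:
    """Generate a tissue phantom lambda stack with ground truth.

    Every pixel's expected spectrum is its region's mixture spectrum scaled to
    ``mean_counts`` (the slide margin gets a flat ``background_counts``
    spectrum); Poisson noise is applied when enabled, and counts are clipped to
    the bit depth.  The same config (and seed) always yields a bit-identical
    stack.
    """
    rng = np.random.default_rng(config.seed)
    labels = _label_image(config, rng)
    axis = config.axis
    nc = axis.n_channels

    spectra = {}
    for name, mix in config.region_mixtures.items():
        spectra[name] = mixture_spectrum(mix, axis, config.components) * config.mean_counts
    spectra["background"] = np.full(nc, config.background_counts / nc)

    expected = np.zeros(config.size + (nc,), dtype=np.float64)
    for name, code in PhantomConfig.LABELS.items():
        if name in spectra:
            expected[labels == code] = spectra[name]

    if config.poisson_noise:
        counts = rng.poisson(expected).astype(np.float64)
    else:
        counts = np.rint(expected)
    maxval = 2**config.bit_depth - 1
    counts = np.clip(counts, 0, maxval)
    dtype = np.uint8 if config.bit_depth <= 8 else np.uint16
    stack = HSIStack(counts.astype(dtype), axis=axis, bit_depth=config.bit_depth)

    region_phasors = {}
    for name, spec_vec in spectra.items():
        one = HSIStack(spec_vec[None, None, :], axis=axis, bit_depth=32)
        f = phasor_transform(one, harmonic=1, intensity_threshold=0.0)
        region_phasors[name] = (float(f.G[0, 0]), float(f.S[0, 0]))

    tiles = None
    if tuple(config.tile_grid) != (1, 1):
        tiles = _cut_tiles(stack, tuple(config.tile_grid), config.overlap_fraction)

    return TissuePhantom(
        stack=stack,
        labels=labels,
        region_phasors=region_phasors,
        region_spectra=spectra,
        config=config,
        tiles=tiles,
    )


@dataclass
class CohortSampleData:
    """One synthetic patient sample with its injected ground truth."""

    sample_id: str
    label: str
    stack: HSIStack
    lesion_mask: np.ndarray
    true_phase_cm: float
    true_modulation_cm: float
    lesion_mixture: Dict[str, float]


def _jitter_weights(
    weights: Dict[str, float], sd: float, rng: np.random.Generator
) -> Dict[str, float]:
    names = list(weights)
    w = np.array([weights[n] for n in names], dtype=np.float64)
    w = np.clip(w + rng.normal(0.0, sd, size=len(w)), 0.01, None)
    w = w / w.sum()
    return dict(zip(names, w))


def make_cohort(
    n_nevus: int = 5,
    n_melanoma: int = 5,
    nevus_profile: Optional[Dict[str, float]] = None,
    melanoma_profile: Optional[Dict[str, float]] = None,
    seed: int = 0,
    size: Tuple[int, int] = (128, 128),
    mean_counts: float = 1000.0,
    jitter_sd: float = 0.03,
    **phantom_kw,
) -> list:
    """Generate a labelled synthetic cohort (default 5 nevi + 5 melanomas).

    Each sample is a tissue phantom whose lesion-nest mixture is the group
    profile perturbed by per-sample weight jitter (between-patient
    variability).  The injected ground truth per sample — the phase and
    modulation of the noiseless lesion mixture spectrum — is recorded so the
    downstream pipeline's recovered centres of mass can be scored against it.
    """
    if n_nevus < 2 or n_melanoma < 2:
        raise ValueError("need at least 2 samples per group for the t-test")
    nevus_profile = dict(nevus_profile or NEVUS_LESION_MIXTURE)
    melanoma_profile = dict(melanoma_profile or MELANOMA_LESION_MIXTURE)
    _check_weights(nevus_profile)
    _check_weights(melanoma_profile)

    rng = np.random.default_rng(seed)
    samples = []
    plan = [("nevus", nevus_profile)] * n_nevus + [
        ("melanoma", melanoma_profile)
    ] * n_melanoma
    for i, (label, profile) in enumerate(plan):
        mix = _jitter_weights(profile, jitter_sd, rng)
        config = PhantomConfig(
            size=size,
            region_mixtures={
                "dermis": dict(DERMIS_MIXTURE),
                "epidermis": dict(EPIDERMIS_MIXTURE),
                "lesion": mix,
            },
            mean_counts=mean_counts,
            seed=int(rng.integers(0, 2**31 - 1)),
            **phantom_kw,
        )
        phantom = make_tissue_phantom(config)
        g, s = phantom.region_phasors["lesion"]
        true_phase = float(np.degrees(np.arctan2(s, g)) % 360.0)
        true_mod = float(np.hypot(g, s))
        samples.append(
            CohortSampleData(
                sample_id=f"{label}{i + 1:02d}",
                label=label,
                stack=phantom.stack,
                lesion_mask=phantom.lesion_mask(),
                true_phase_cm=true_phase,
                true_modulation_cm=true_mod,
                lesion_mixture=mix,
            )
        )
    return samples


def component_fingerprints(
    axis: Optional[SpectralAxis] = None,
    components: Dict[str, ComponentSpec] = DEFAULT_COMPONENTS,
) -> list:
    """Phasor fingerprints of the pure component library on an axis."""
    from .fingerprints import ComponentFingerprint

    axis = axis or SpectralAxis.default()
    out = []
    for name, spec in components.items():
        vec = make_spectrum(replace(spec, brightness=1.0), axis)
        if vec.sum() == 0:
            continue
        one = HSIStack(vec[None, None, :], axis=axis, bit_depth=32)
        f = phasor_transform(one, harmonic=1, intensity_threshold=0.0)
        out.append(
            ComponentFingerprint(
                name=name,
                centroid=(float(f.G[0, 0]), float(f.S[0, 0])),
                source_spectrum=vec,
                axis=axis,
            )
        )
    return out
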