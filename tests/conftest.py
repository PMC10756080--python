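import numpy as np
import pytest

from hsiphasor import HSIStack, PhasorField, SpectralAxis, phasor_transform


@pytest.fixture
def axis():
    """The default acquisition axis: 423-723 nm in 30 channels."""
    return SpectralAxis.default()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def gaussian(peak, fwhm):
    """Gaussian emission model as a callable over wavelength (nm)."""
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return lambda lam: np.exp(-0.5 * ((lam - peak) / sigma) ** 2)


def quadrature_phasor(spectrum_fn, axis, harmonic=1, npts=10_000):
    """Independent dense-grid numerical-integration oracle for (G, S).

    Trapezoid quadrature of the continuous phasor integrals on ``npts``
    wavelength samples; kept free of any package transform code.
    """
    lam = np.linspace(axis.lambda_min, axis.lambda_max, npts)
    I = spectrum_fn(lam)
    x = (lam - axis.lambda_min) / (axis.lambda_max - axis.lambda_min)
    denom = np.trapezoid(I, lam)
    G = np.trapezoid(I * np.cos(2 * np.pi * harmonic * x), lam) / denom
    S = np.trapezoid(I * np.sin(2 * np.pi * harmonic * x), lam) / denom
    return G, S


def single_pixel_field(spectrum, axis, threshold=0.0):
    """Phasor field of one pixel holding the given channel spectrum."""
    stack = HSIStack(np.asarray(spectrum, dtype=float)[None, None, :], axis=axis)
    return phasor_transform(stack, intensity_threshold=threshold)


def uniform_field(G, S, shape=(4, 4)):
    """A phasor field with every pixel at the same (G, S)."""
    g = np.full(shape, float(G))
    s = np.full(shape, float(S))
    return PhasorField(
        G=g,
        S=s,
        total_intensity=np.ones(shape),
        valid_mask=np.ones(shape, dtype=bool),
    )
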