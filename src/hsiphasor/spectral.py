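"""Discrete spectral phasor transform, polar conversion and wavelength calibration.

The spectral phasor of a pixel's emission spectrum :math:`I(\\lambda)` recorded
on the wavelength window :math:`[\\lambda_{min}, \\lambda_{max}]` is the pair of
normalised first-harmonic Fourier coefficients

.. math::

    G = \\frac{\\sum_k I_k \\cos(2\\pi n\\, x_k)}{\\sum_k I_k}, \\qquad
    S = \\frac{\\sum_k I_k \\sin(2\\pi n\\, x_k)}{\\sum_k I_k},

where :math:`x_k = (\\lambda_k - \\lambda_{min})/(\\lambda_{max} -
\\lambda_{min})` is the fractional spectral position of channel *k* and *n* is
the harmonic (1 throughout this package).  Every nonnegative spectrum maps
inside the unit disc; a monochromatic line lands on the unit circle, a
spectrally flat spectrum at the origin.  The polar form of (G, S) — phase and
modulation — encodes the spectrum's centre of mass and width respectively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SpectralAxis",
    "HSIStack",
    "PhasorField",
    "PhaseModulationMaps",
    "phasor_transform",
    "phase_modulation",
    "phase_to_wavelength",
    "wavelength_to_phase",
    "modal_background_threshold",
]

#: default acquisition axis: 423-723 nm in 30 channels of 10 nm
DEFAULT_AXIS_PARAMS = (423.0, 723.0, 30)


@dataclass(frozen=True)
class SpectralAxis:
    """Uniform wavelength grid defining the phasor period.

    Channel centres follow the mid-bin convention,
    ``center[k] = lambda_min + (k + 0.5) * delta`` with
    ``delta = (lambda_max - lambda_min) / n_channels``, so a spectrally flat
    spectrum maps exactly to the phasor origin and, on the default
    423-723 nm / 30-channel axis, 498 nm (phase 90 deg) is an exact channel
    centre.
    """

    lambda_min: float
    lambda_max: float
    n_channels: int

    def __post_init__(self) -> None:
        if not self.lambda_max > self.lambda_min:
            raise ValueError(
                f"lambda_max ({self.lambda_max}) must exceed lambda_min "
                f"({self.lambda_min})"
            )
        if self.n_channels < 1:
            raise ValueError(f"n_channels must be positive, got {self.n_channels}")

    @property
    def span(self) -> float:
        return self.lambda_max - self.lambda_min

    @property
    def channel_width(self) -> float:
        return self.span / self.n_channels

    @property
    def channel_centers(self) -> np.ndarray:
        k = np.arange(self.n_channels)
        return self.lambda_min + (k + 0.5) * self.channel_width

    @property
    def positions(self) -> np.ndarray:
        """Fractional spectral positions x_k in (0, 1) of the channel centres."""
        return (self.channel_centers - self.lambda_min) / self.span

    @classmethod
    def default(cls) -> "SpectralAxis":
        return cls(*DEFAULT_AXIS_PARAMS)


@dataclass
class HSIStack:
    """A lambda stack: per-pixel nonnegative intensity spectra on a SpectralAxis.

    ``intensities`` has shape (rows, cols, n_channels).
    """

    intensities: np.ndarray
    axis: SpectralAxis
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError(
                f"intensities must be 3-D (rows, cols, channels); "
                f"got shape {self.intensities.shape}"
            )
        if self.intensities.shape[2] != self.axis.n_channels:
            raise ValueError(
                f"stack has {self.intensities.shape[2]} channels but the "
                f"spectral axis defines {self.axis.n_channels}"
            )
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be nonnegative")

    @property
    def shape(self) -> tuple:
        return self.intensities.shape[:2]

    def total_intensity(self) -> np.ndarray:
        return self.intensities.sum(axis=2, dtype=np.float64)


@dataclass
class PhasorField:
    """Per-pixel phasor coordinates (G, S) with total intensity and validity mask.

    Invalid pixels (total intensity below the acquisition threshold, or an
    undefined phasor) carry G = S = 0 and are excluded from all downstream
    statistics via ``valid_mask``.
    """

    G: np.ndarray
    S: np.ndarray
    total_intensity: np.ndarray
    valid_mask: np.ndarray
    harmonic: int = 1
    axis: Optional[SpectralAxis] = None
    intensity_threshold: float = 0.0

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.G, self.S, self.total_intensity, self.valid_mask)}
        if len(shapes) != 1:
            raise ValueError(f"phasor planes have mismatched shapes: {shapes}")

    @property
    def shape(self) -> tuple:
        return self.G.shape

    def valid_points(self) -> np.ndarray:
        """(N, 2) array of valid (G, S) pairs."""
        return np.column_stack([self.G[self.valid_mask], self.S[self.valid_mask]])

    def copy(self) -> "PhasorField":
        return PhasorField(
            self.G.copy(), self.S.copy(), self.total_intensity.copy(),
            self.valid_mask.copy(), self.harmonic, self.axis,
            self.intensity_threshold,
        )


@dataclass
class PhaseModulationMaps:
    """Per-pixel polar phasor coordinates.

    ``phase`` in degrees in [0, 360), counterclockwise from (1, 0);
    ``modulation`` dimensionless in [0, 1].  Pixels where the phasor is at the
    exact origin have no defined phase and are flagged invalid.
    """

    phase: np.ndarray
    modulation: np.ndarray
    valid_mask: np.ndarray


def modal_background_threshold(stack: HSIStack, factor: float = 3.0) -> float:
    """Intensity threshold as ``factor`` x the modal total count of the stack.

    The mode of the per-pixel total-intensity histogram estimates the blank
    (slide/background) level when a dark background is present in the field of
    view; the default acquisition threshold is three times that level.  For
    images with no background the mode sits on tissue and this heuristic
    over-masks — pass an explicit threshold in that case.
    """
    totals = np.rint(stack.total_intensity()).astype(np.int64).ravel()
    if totals.size == 0:
        return 0.0
    mode = np.bincount(totals).argmax()
    return factor * float(mode)


def phasor_transform(
    stack: HSIStack,
    harmonic: int = 1,
    intensity_threshold: float | str = "auto",
) -> PhasorField:
    """Compute the per-pixel spectral phasor field of a lambda stack.

    Parameters
    ----------
    stack : HSIStack
        Input lambda stack.
    harmonic : int
        Fourier harmonic n >= 1 (1 for all analyses here).
    intensity_threshold : float or "auto"
        Pixels whose total counts fall below this value are masked invalid.
        ``"auto"`` uses :func:`modal_background_threshold`.  Zero-intensity
        pixels are always invalid (their phasor is undefined).

    Returns
    -------
    PhasorField
    """
    if harmonic < 1:
        raise ValueError(f"harmonic must be >= 1, got {harmonic}")
    if intensity_threshold == "auto":
        threshold = modal_background_threshold(stack)
    else:
        threshold = float(intensity_threshold)

    x = stack.axis.positions
    ang = 2.0 * np.pi * harmonic * x
    I = stack.intensities.astype(np.float64, copy=False)
    totals = I.sum(axis=2)
    valid = (totals >= threshold) & (totals > 0)

    with np.errstate(invalid="ignore", divide="ignore"):
        G = I @ np.cos(ang) / totals
        S = I @ np.sin(ang) / totals
    G = np.where(valid, G, 0.0)
    S = np.where(valid, S, 0.0)

    return PhasorField(
        G=G, S=S, total_intensity=totals, valid_mask=valid,
        harmonic=harmonic, axis=stack.axis, intensity_threshold=threshold,
    )


def phase_modulation(fld: PhasorField) -> PhaseModulationMaps:
    """Polar form of a phasor field.

    phase = atan2(S, G) mapped to [0, 360) degrees; modulation = sqrt(G^2+S^2).
    A pixel at the exact phasor origin has an undefined phase and is flagged
    invalid rather than silently assigned 0 degrees.
    """
    at_origin = np.hypot(fld.G, fld.S) < 1e-12
    valid = fld.valid_mask & ~at_origin
    n_dropped = int(np.count_nonzero(fld.valid_mask & at_origin))
    if n_dropped:
        logger.warning(
            "%d pixel(s) at the phasor origin have undefined phase; flagged invalid",
            n_dropped,
        )
    phase = np.degrees(np.arctan2(fld.S, fld.G)) % 360.0
    modulation = np.hypot(fld.G, fld.S)
    phase = np.where(valid, phase, 0.0)
    modulation = np.where(valid, modulation, 0.0)
    return PhaseModulationMaps(phase=phase, modulation=modulation, valid_mask=valid)


def phase_to_wavelength(
    phase: float | np.ndarray, axis: SpectralAxis, harmonic: int = 1
) -> float | np.ndarray:
    """Map a phasor phase (degrees) to the emission wavelength it calibrates to.

    lambda = lambda_min + span * phase / (360 * n).  On the default axis,
    90 deg -> 498 nm and 180 deg -> 573 nm.  Phases outside [0, 360) are
    wrapped (with a log warning).
    """
    phase = np.asarray(phase, dtype=np.float64)
    if np.any((phase < 0) | (phase >= 360.0)):
        logger.warning("phase outside [0, 360) wrapped modulo 360")
        phase = phase % 360.0
    lam = axis.lambda_min + axis.span * phase / (360.0 * harmonic)
    return float(lam) if lam.ndim == 0 else lam


def wavelength_to_phase(
    wavelength: float | np.ndarray, axis: SpectralAxis, harmonic: int = 1
) -> float | np.ndarray:
    """Inverse of :func:`phase_to_wavelength` (exact round-trip)."""
    wavelength = np.asarray(wavelength, dtype=np.float64)
    phase = (wavelength - axis.lambda_min) / axis.span * 360.0 * harmonic
    return float(phase) if phase.ndim == 0 else phase
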