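"""Phasor-space segmentation and visualization: the reciprocity principle.

Because the phasor transform is unique per spectrum, a geometric selector
("cursor") drawn in phasor space picks out exactly the image pixels whose
spectra fall in that spectral neighbourhood; conversely an image-space region
of interest restricts the phasor cloud to its own pixels (the "secondary
phasor").  This module implements cursors, the 2-D phasor histogram,
invalid-aware median denoising of the G/S planes, and pseudocolour phase maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from matplotlib.colors import hsv_to_rgb
from matplotlib.path import Path as MplPath
from numpy.lib.stride_tricks import sliding_window_view
from shapely.geometry import Polygon as ShapelyPolygon

from .spectral import PhasorField, phase_modulation

__all__ = [
    "Cursor",
    "CircleCursor",
    "PolygonCursor",
    "PhaseWedgeCursor",
    "ROIMask",
    "PhasorHistogram2D",
    "median_filter_phasor",
    "phasor_histogram",
    "pseudocolor_phase",
    "select_by_cursor",
    "phasor_of_roi",
]


class Cursor:
    """A geometric selector in (G, S) phasor space; boundary points included."""

    def contains(self, G: np.ndarray, S: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def to_dict(self) -> dict:
        raise NotImplementedError

    @staticmethod
    def from_dict(d: dict) -> "Cursor":
        kind = d["kind"]
        if kind == "circle":
            return CircleCursor(tuple(d["center"]), d["radius"])
        if kind == "polygon":
            return PolygonCursor([tuple(v) for v in d["vertices"]])
        if kind == "phase_wedge":
            return PhaseWedgeCursor(
                d["phase_lo"], d["phase_hi"], d.get("mod_lo", 0.0), d.get("mod_hi", 1.0)
            )
        raise ValueError(f"unknown cursor kind {kind!r}")


@dataclass
class CircleCursor(Cursor):
    center: tuple
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"cursor radius must be > 0, got {self.radius}")

    def contains(self, G, S):
        return np.hypot(G - self.center[0], S - self.center[1]) <= self.radius

    def to_dict(self):
        return {"kind": "circle", "center": list(self.center), "radius": self.radius}


@dataclass
class PolygonCursor(Cursor):
    vertices: list

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError("polygon cursor needs at least 3 vertices")
        if not ShapelyPolygon(self.vertices).is_valid:
            raise ValueError("polygon cursor is self-intersecting or degenerate")
        self._path = MplPath(np.asarray(self.vertices, dtype=float), closed=False)

    def contains(self, G, S):
        pts = np.column_stack([np.ravel(G), np.ravel(S)])
        # tiny positive radius makes the boundary inclusive
        inside = self._path.contains_points(pts, radius=1e-9)
        inside |= self._path.contains_points(pts, radius=-1e-9)
        return inside.reshape(np.shape(G))

    def to_dict(self):
        return {"kind": "polygon", "vertices": [list(v) for v in self.vertices]}


@dataclass
class PhaseWedgeCursor(Cursor):
    """An annular wedge in polar phasor coordinates (degrees / modulation)."""

    phase_lo: float
    phase_hi: float
    mod_lo: float = 0.0
    mod_hi: float = 1.0

    def __post_init__(self) -> None:
        if not self.phase_lo < self.phase_hi:
            raise ValueError(
                f"phase_lo ({self.phase_lo}) must be < phase_hi ({self.phase_hi})"
            )
        if not 0 <= self.mod_lo < self.mod_hi:
            raise ValueError("need 0 <= mod_lo < mod_hi")

    def contains(self, G, S):
        phase = np.degrees(np.arctan2(S, G)) % 360.0
        mod = np.hypot(G, S)
        return (
            (phase >= self.phase_lo)
            & (phase <= self.phase_hi)
            & (mod >= self.mod_lo)
            & (mod <= self.mod_hi)
        )

    def to_dict(self):
        return {
            "kind": "phase_wedge",
            "phase_lo": self.phase_lo,
            "phase_hi": self.phase_hi,
            "mod_lo": self.mod_lo,
            "mod_hi": self.mod_hi,
        }


@dataclass
class ROIMask:
    """A boolean image-space region of interest with provenance."""

    mask: np.ndarray
    provenance: str = "hand-drawn"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class PhasorHistogram2D:
    """Counts of valid pixels on a square (G, S) bin grid over [-1, 1]^2."""

    counts: np.ndarray
    g_edges: np.ndarray
    s_edges: np.ndarray

    @property
    def bin_count(self) -> int:
        return self.counts.shape[0]


def median_filter_phasor(
    fld: PhasorField, kernel: int = 3, repeats: int = 1
) -> PhasorField:
    """Median-filter the G and S planes to tighten phasor clusters.

    The median over each kernel window is taken over *valid* neighbours only,
    so masked pixels neither contribute nor spread; total intensity and the
    validity mask are left untouched.  This is the standard phasor-space
    denoising step: it reduces the scatter of a material's cluster without
    shifting a homogeneous region's phasor.
    """
    if kernel % 2 == 0 or kernel < 3:
        raise ValueError(f"kernel must be an odd integer >= 3, got {kernel}")
    if repeats < 0:
        raise ValueError("repeats must be >= 0")

    out = fld.copy()
    pad = kernel // 2
    for _ in range(repeats):
        for name in ("G", "S"):
            plane = getattr(out, name)
            work = np.where(out.valid_mask, plane, np.nan)
            work = np.pad(work, pad, constant_values=np.nan)
            windows = sliding_window_view(work, (kernel, kernel))
            with warnings.catch_warnings():
                warnings.filterwarnings("ignore", "All-NaN slice", RuntimeWarning)
                med = np.nanmedian(windows, axis=(-2, -1))
            # pixels with no valid neighbour keep their value
            med = np.where(np.isnan(med), plane, med)
            setattr(out, name, np.where(out.valid_mask, med, plane))
    return out


def phasor_histogram(fld: PhasorField, bins: int = 128) -> PhasorHistogram2D:
    """2-D histogram of valid pixels on the [-1, 1]^2 phasor plane."""
    pts = fld.valid_points()
    counts, g_edges, s_edges = np.histogram2d(
        pts[:, 0], pts[:, 1], bins=bins, range=[[-1.0, 1.0], [-1.0, 1.0]]
    )
    return PhasorHistogram2D(counts=counts, g_edges=g_edges, s_edges=s_edges)


def pseudocolor_phase(
    fld: PhasorField,
    phase_range: tuple = (45.0, 180.0),
    hue_range: tuple = (0.0, 5.0 / 6.0),
) -> np.ndarray:
    """Pseudocolour RGB image of the per-pixel phasor phase.

    Each valid pixel's phase is mapped linearly from ``phase_range`` onto a hue
    sweep (default red -> violet); phases outside the range clamp to the
    endpoints and invalid pixels render black.

    Returns an (rows, cols, 3) float RGB array in [0, 1].
    """
    lo, hi = phase_range
    if not 0 <= lo < 360 and 0 <= hi < 360:
        raise ValueError("phase_range must lie within [0, 360)")
    if hi == lo:
        raise ValueError("degenerate phase_range (lo == hi)")
    if hi < lo:
        raise ValueError("phase_range must be increasing")

    pm = phase_modulation(fld)
    frac = np.clip((pm.phase - lo) / (hi - lo), 0.0, 1.0)
    hue = hue_range[0] + frac * (hue_range[1] - hue_range[0])
    hsv = np.stack([hue, np.ones_like(hue), np.ones_like(hue)], axis=-1)
    rgb = hsv_to_rgb(hsv)
    rgb[~pm.valid_mask] = 0.0
    return rgb


def select_by_cursor(fld: PhasorField, cursor: Cursor) -> ROIMask:
    """Image-space mask of the valid pixels whose phasor lies inside the cursor."""
    inside = cursor.contains(fld.G, fld.S)
    return ROIMask(mask=fld.valid_mask & inside, provenance="cursor")


def phasor_of_roi(fld: PhasorField, roi) -> PhasorField:
    """Restrict a phasor field to an image-space ROI (the secondary phasor)."""
    mask = roi.mask if isinstance(roi, ROIMask) else np.asarray(roi, dtype=bool)
    if mask.shape != fld.shape:
        raise ValueError(
            f"ROI shape {mask.shape} does not match field shape {fld.shape}"
        )
    out = fld.copy()
    out.valid_mask = fld.valid_mask & mask
    out.G = np.where(out.valid_mask, out.G, 0.0)
    out.S = np.where(out.valid_mask, out.S, 0.0)
    return out
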