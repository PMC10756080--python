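"""Pure-component phasor fingerprints and linear-combination unmixing.

The phasor of a mixture of emitters is the intensity-weighted convex
combination of the pure emitters' phasors: a two-component mixture lies on the
segment joining the pure fingerprints, a three-component mixture inside their
triangle.  Fractions recovered here are therefore *emitted-intensity*
fractions (shares of detected photons), not molar concentrations — converting
to concentrations would require the components' brightness, which label-free
tissue data does not provide.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .phasor_image import PhasorHistogram2D
from .spectral import PhasorField, SpectralAxis

__all__ = [
    "ComponentFingerprint",
    "component_centroid",
    "unmix_two",
    "unmix_three",
    "overlay_fingerprints",
    "save_fingerprint_library",
    "load_fingerprint_library",
]

_DEGENERATE_TOL = 1e-9


@dataclass
class ComponentFingerprint:
    """A named pure-component phasor position with its (optional) source spectrum."""

    name: str
    centroid: tuple
    source_spectrum: Optional[np.ndarray] = None
    axis: Optional[SpectralAxis] = None

    def __post_init__(self) -> None:
        g, s = self.centroid
        if g * g + s * s > 1.0 + 1e-9:
            raise ValueError(
                f"fingerprint {self.name!r} centroid {self.centroid} lies "
                "outside the unit disc"
            )

    @property
    def gs(self) -> np.ndarray:
        return np.asarray(self.centroid, dtype=np.float64)


def _as_gs(p) -> np.ndarray:
    if isinstance(p, ComponentFingerprint):
        return p.gs
    return np.asarray(p, dtype=np.float64)


def component_centroid(
    fld: PhasorField, k: int, seed: int = 0, n_init: int = 10
) -> list:
    """k-means centroid(s) of the valid phasor cloud.

    For k = 1 this is the arithmetic mean of (G, S) — the cluster centroid
    minimizing inertia.  Centroids are returned sorted by phase angle for
    reproducible ordering.
    """
    pts = fld.valid_points()
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(pts) < k:
        raise ValueError(f"k = {k} exceeds the {len(pts)} valid pixels")
    if k == 1:
        return [tuple(pts.mean(axis=0))]
    km = KMeans(n_clusters=k, random_state=seed, n_init=n_init)
    km.fit(pts)
    centers = km.cluster_centers_
    order = np.argsort(np.arctan2(centers[:, 1], centers[:, 0]) % (2 * np.pi))
    return [tuple(c) for c in centers[order]]


@dataclass
class TwoComponentFractions:
    fraction_a: float
    residual: float


@dataclass
class ThreeComponentFractions:
    fractions: np.ndarray
    outside: bool


def unmix_two(p, a, b) -> TwoComponentFractions:
    """Intensity fraction of component ``a`` in the phasor ``p`` on segment a-b.

    ``p`` is orthogonally projected onto the segment joining the two pure
    fingerprints; the fraction is the projected point's relative distance from
    ``b``, clamped to [0, 1].  ``residual`` is the distance from ``p`` to the
    (clamped) projection — a large residual flags a pixel not explained by
    these two components.
    """
    p, a, b = _as_gs(p), _as_gs(a), _as_gs(b)
    d = a - b
    L2 = float(d @ d)
    if L2 < _DEGENERATE_TOL**2:
        raise ValueError("degenerate fingerprint pair: |a - b| below 1e-9")
    t = float((p - b) @ d) / L2
    t = min(max(t, 0.0), 1.0)
    proj = b + t * d
    return TwoComponentFractions(fraction_a=t, residual=float(np.linalg.norm(p - proj)))


def unmix_three(p, a, b, c) -> ThreeComponentFractions:
    """Barycentric intensity fractions of ``p`` in the triangle (a, b, c).

    Fractions sum to 1.  A phasor outside the triangle yields a negative
    barycentric coordinate: the ``outside`` flag is set and the fractions are
    clamped to zero and renormalized.
    """
    p, a, b, c = (_as_gs(x) for x in (p, a, b, c))
    T = np.column_stack([a - c, b - c])
    det = float(np.linalg.det(T))
    if abs(det) < _DEGENERATE_TOL:
        raise ValueError(
            "collinear fingerprint triple: use unmix_two on the spanning pair"
        )
    lam = np.linalg.solve(T, p - c)
    frac = np.array([lam[0], lam[1], 1.0 - lam[0] - lam[1]])
    outside = bool(np.any(frac < -1e-12))
    if outside:
        frac = np.clip(frac, 0.0, None)
        frac = frac / frac.sum()
    return ThreeComponentFractions(fractions=frac, outside=outside)


def overlay_fingerprints(
    histogram: PhasorHistogram2D,
    library: Sequence[ComponentFingerprint],
    path=None,
    title: str = "Phasor plot with component fingerprints",
):
    """Render the phasor histogram with labelled pure-component centroids.

    Returns the matplotlib Figure; writes it to ``path`` if given.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    extent = [
        histogram.g_edges[0],
        histogram.g_edges[-1],
        histogram.s_edges[0],
        histogram.s_edges[-1],
    ]
    ax.imshow(
        np.log1p(histogram.counts).T,
        origin="lower",
        extent=extent,
        cmap="viridis",
        aspect="equal",
    )
    theta = np.linspace(0, 2 * np.pi, 361)
    ax.plot(np.cos(theta), np.sin(theta), color="0.7", lw=0.8)
    for fp in library:
        g, s = fp.centroid
        ax.plot(g, s, "o", color="red", ms=5)
        ax.annotate(fp.name, (g, s), textcoords="offset points", xytext=(4, 4),
                    color="white", fontsize=8)
    ax.set_xlabel("G")
    ax.set_ylabel("S")
    ax.set_title(title)
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


_LIBRARY_COLUMNS = ["name", "G", "S", "lambda_min", "lambda_max", "n_channels", "harmonic"]


def save_fingerprint_library(
    library: Sequence[ComponentFingerprint],
    path,
    axis: SpectralAxis,
    harmonic: int = 1,
) -> None:
    """Write a fingerprint library as CSV (name, G, S, axis, harmonic)."""
    rows = [
        {
            "name": fp.name,
            "G": fp.centroid[0],
            "S": fp.centroid[1],
            "lambda_min": axis.lambda_min,
            "lambda_max": axis.lambda_max,
            "n_channels": axis.n_channels,
            "harmonic": harmonic,
        }
        for fp in library
    ]
    pd.DataFrame(rows, columns=_LIBRARY_COLUMNS).to_csv(path, index=False)


def load_fingerprint_library(path) -> list:
    """Read a fingerprint library CSV written by :func:`save_fingerprint_library`."""
    df = pd.read_csv(path)
    missing = set(_LIBRARY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"fingerprint library missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        axis = SpectralAxis(row["lambda_min"], row["lambda_max"], int(row["n_channels"]))
        out.append(
            ComponentFingerprint(
                name=str(row["name"]), centroid=(row["G"], row["S"]), axis=axis
            )
        )
    return out


def default_fingerprint_library() -> list:
    """The packaged default component library (synthetic stand-in spectra)."""
    data = Path(__file__).parent / "data" / "fingerprints_default.csv"
    return load_fingerprint_library(data)
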