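"""Reading and writing lambda stacks, tiled acquisitions, and phasor fields.

Lambda stacks travel as multi-page TIFF / OME-TIFF with one page per spectral
channel, pages ordered by ascending wavelength.  Whole-slide acquisitions
arrive as rectangular tile grids with a fractional overlap (5% by default)
which are reassembled by channel-wise averaging of the overlap strips.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

from .spectral import HSIStack, PhasorField, SpectralAxis

__all__ = [
    "TileSet",
    "read_stack",
    "write_stack",
    "stitch_tiles",
    "save_phasor_field",
    "load_phasor_field",
]


@dataclass
class TileSet:
    """A rectangular grid of lambda-stack tiles sharing one spectral axis.

    ``grid_positions[i]`` is the (row, col) grid index of ``tiles[i]``;
    ``overlap_fraction`` is the fraction of each tile edge shared with its
    neighbour (default 0.05).
    """

    tiles: list
    grid_positions: list
    overlap_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_fraction < 0.5:
            raise ValueError(
                f"overlap_fraction must be in [0, 0.5), got {self.overlap_fraction}"
            )
        if len(self.tiles) != len(self.grid_positions):
            raise ValueError("tiles and grid_positions length mismatch")
        if not self.tiles:
            raise ValueError("empty tile set")
        ref = self.tiles[0]
        for t in self.tiles[1:]:
            if t.intensities.shape != ref.intensities.shape:
                raise ValueError(
                    f"inconsistent tile shapes: {t.intensities.shape} vs "
                    f"{ref.intensities.shape}"
                )
            if t.axis != ref.axis:
                raise ValueError("tiles do not share a single spectral axis")


def read_stack(path, axis: SpectralAxis, bit_depth: int | None = None) -> HSIStack:
    """Read a multi-page/multi-channel TIFF lambda stack.

    The page (or channel) count must equal ``axis.n_channels``; pages are taken
    in ascending-wavelength order.  8-bit and 16-bit integer data are accepted
    as-is; floating point is accepted for synthetic/intermediate data.
    """
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D lambda stack, got shape {arr.shape}")
    # channel-first (pages) is the on-disk layout; tolerate channel-last
    if arr.shape[0] == axis.n_channels:
        arr = np.moveaxis(arr, 0, -1)
    elif arr.shape[2] != axis.n_channels:
        raise ValueError(
            f"{path}: file has {arr.shape[0]} pages/channels but the spectral "
            f"axis defines {axis.n_channels}"
        )
    if bit_depth is None:
        bit_depth = arr.dtype.itemsize * 8 if arr.dtype.kind in "ui" else 32
    return HSIStack(intensities=arr, axis=axis, bit_depth=bit_depth)


def write_stack(stack: HSIStack, path) -> None:
    """Write a lambda stack as a multi-page TIFF (one page per channel)."""
    pages = np.moveaxis(stack.intensities, -1, 0)
    tifffile.imwrite(Path(path), pages, photometric="minisblack")


def _overlap_pixels(tile_len: int, overlap_fraction: float) -> int:
    return int(round(tile_len * overlap_fraction))


def stitch_tiles(tileset: TileSet) -> HSIStack:
    """Reassemble a rectangular tile grid into one mosaic stack.

    Overlapping pixels are averaged channel-wise; the mosaic keeps the tiles'
    spectral axis.  Missing grid positions raise an error listing the gaps.
    """
    positions = [tuple(p) for p in tileset.grid_positions]
    rows = max(p[0] for p in positions) + 1
    cols = max(p[1] for p in positions) + 1
    expected = {(r, c) for r in range(rows) for c in range(cols)}
    missing = sorted(expected - set(positions))
    if missing:
        raise ValueError(f"missing grid positions: {missing}")
    if len(set(positions)) != len(positions):
        raise ValueError("duplicate grid positions")

    ref = tileset.tiles[0]
    th, tw, nc = ref.intensities.shape
    oh = _overlap_pixels(th, tileset.overlap_fraction)
    ow = _overlap_pixels(tw, tileset.overlap_fraction)
    step_h, step_w = th - oh, tw - ow
    H = step_h * (rows - 1) + th
    W = step_w * (cols - 1) + tw

    acc = np.zeros((H, W, nc), dtype=np.float64)
    cnt = np.zeros((H, W, 1), dtype=np.float64)
    for tile, (r, c) in zip(tileset.tiles, positions):
        y, x = r * step_h, c * step_w
        acc[y : y + th, x : x + tw] += tile.intensities
        cnt[y : y + th, x : x + tw] += 1.0
    mosaic = acc / cnt
    return HSIStack(intensities=mosaic, axis=ref.axis, bit_depth=ref.bit_depth)


def save_phasor_field(fld: PhasorField, path) -> None:
    """Serialize a phasor field as a 3-plane float TIFF plus a JSON sidecar.

    Planes are (G, S, total intensity); invalid pixels carry NaN in the G and S
    planes.  The sidecar records the spectral axis, harmonic and intensity
    threshold for provenance.
    """
    path = Path(path)
    G = np.where(fld.valid_mask, fld.G, np.nan).astype(np.float32)
    S = np.where(fld.valid_mask, fld.S, np.nan).astype(np.float32)
    planes = np.stack([G, S, fld.total_intensity.astype(np.float32)])
    tifffile.imwrite(path, planes, photometric="minisblack")
    sidecar = {
        "harmonic": fld.harmonic,
        "intensity_threshold": fld.intensity_threshold,
        "axis": None
        if fld.axis is None
        else {
            "lambda_min": fld.axis.lambda_min,
            "lambda_max": fld.axis.lambda_max,
            "n_channels": fld.axis.n_channels,
        },
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_phasor_field(path) -> PhasorField:
    """Read a phasor field written by :func:`save_phasor_field`."""
    path = Path(path)
    planes = tifffile.imread(path)
    if planes.shape[0] != 3:
        raise ValueError(f"{path}: expected 3 planes (G, S, intensity)")
    G, S, total = (planes[i].astype(np.float64) for i in range(3))
    valid = ~np.isnan(G)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    axis = None
    if meta.get("axis"):
        a = meta["axis"]
        axis = SpectralAxis(a["lambda_min"], a["lambda_max"], a["n_channels"])
    return PhasorField(
        G=np.where(valid, G, 0.0),
        S=np.where(valid, S, 0.0),
        total_intensity=total,
        valid_mask=valid,
        harmonic=int(meta.get("harmonic", 1)),
        axis=axis,
        intensity_threshold=float(meta.get("intensity_threshold", 0.0)),
    )
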