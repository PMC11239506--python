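"""Lateral tiling for deconvolving images larger than memory.

The lateral (x, y) domain is split into a grid of core rectangles that
partition the image exactly.  Each tile is read with an extra overlap
padding p on every side that has a neighbor (clipped at image borders),
deconvolved independently with the full axial extent, and written back with
per-pixel weights that ramp linearly across the overlap band so that the
weights of all tiles covering a pixel sum to one.  Tiles are streamed
through a raw 32-bit float scratch file: peak resident memory scales with
the tile volume, not the image volume.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from .deconv import DeconvConfig, shb_iterate
from .psf import PSFVolume

__all__ = ["Tile", "TileGrid", "plan_tiles", "blend_weights", "deconvolve_tiled"]


@dataclass(frozen=True)
class Tile:
    """One lateral tile: half-open pixel intervals, core inside padded."""

    core: tuple[tuple[int, int], tuple[int, int]]  # ((y0, y1), (x0, x1))
    padded: tuple[tuple[int, int], tuple[int, int]]


@dataclass(frozen=True)
class TileGrid:
    T: int
    p: int
    image_shape: tuple[int, int, int]  # (nz, ny, nx)
    tiles: tuple[Tile, ...]


def _axis_cores(extent: int, T: int, p: int) -> list[tuple[int, int]]:
    """Near-equal core intervals whose padded size stays within T."""
    usable = T - 2 * p
    n = max(1, -(-extent // usable))  # ceil
    size = -(-extent // n)
    edges = [min(i * size, extent) for i in range(n + 1)]
    return [(edges[i], edges[i + 1]) for i in range(n) if edges[i] < edges[i + 1]]


def plan_tiles(image_shape: tuple[int, int, int], T: int, p: int) -> TileGrid:
    """Plan the lateral tile grid for an image of shape (nz, ny, nx).

    T is the maximum allowed padded tile side in pixels, p the overlap
    padding.  Cores partition each lateral axis exactly; padded regions are
    the cores dilated by p and clipped to the image.  Raises on T <= 2p.
    """
    if T <= 2 * p:
        raise ValueError(f"tile size T={T} must exceed twice the padding p={p}")
    nz, ny, nx = image_shape
    if min(ny, nx) < 1 or nz < 1:
        raise ValueError("image extents must be positive")
    ycores = _axis_cores(ny, T, p)
    xcores = _axis_cores(nx, T, p)
    tiles = []
    for y0, y1 in ycores:
        for x0, x1 in xcores:
            pad = (
                (max(0, y0 - p), min(ny, y1 + p)),
                (max(0, x0 - p), min(nx, x1 + p)),
            )
            tiles.append(Tile(core=((y0, y1), (x0, x1)), padded=pad))
    return TileGrid(T=T, p=p, image_shape=image_shape, tiles=tuple(tiles))


def _axis_weight(n_img: int, core: tuple[int, int], pad: tuple[int, int], p: int) -> np.ndarray:
    """1D blend weight over the padded interval of one axis.

    Ramps linearly from 0 at the outer padded edge to 1 at distance 2p from
    it, centered on the core boundary, so two neighboring ramps sum to 1 at
    every pixel.  Where the tile touches the image border there is no
    neighbor and the weight is 1 up to the border.
    """
    (c0, c1), (t0, t1) = core, pad
    x = np.arange(t0, t1, dtype=np.float64)
    w = np.ones(t1 - t0)
    if p > 0:
        if c0 > 0:  # left neighbor: ramp up across [c0 - p, c0 + p)
            w = np.minimum(w, np.clip((x - (c0 - p) + 0.5) / (2 * p), 0.0, 1.0))
        if c1 < n_img:  # right neighbor: ramp down across [c1 - p, c1 + p)
            w = np.minimum(w, np.clip(((c1 + p) - x - 0.5) / (2 * p), 0.0, 1.0))
    return w


def blend_weights(tile: Tile, grid: TileGrid) -> np.ndarray:
    """Lateral (ny, nx) blend-weight map for one padded tile."""
    _, ny, nx = grid.image_shape
    wy = _axis_weight(ny, tile.core[0], tile.padded[0], grid.p)
    wx = _axis_weight(nx, tile.core[1], tile.padded[1], grid.p)
    return np.outer(wy, wx)


def deconvolve_tiled(
    image_source,
    psf: PSFVolume,
    cfg: DeconvConfig,
    scratch_dir: str | None = None,
) -> np.ndarray:
    """Deconvolve a large image tile by tile.

    ``image_source`` is any 3D sliceable with a ``.shape`` attribute (an
    ndarray or a ``numpy.memmap`` over a raw file); tiles are read on
    demand, deconvolved with the full axial extent and accumulated into a
    float32 scratch memmap with blend weighting.  A second scratch memmap
    accumulates the weight sum, which also guards partition of unity when
    cores are narrower than 2p.  Returns the assembled float32 volume
    (memmap when a scratch directory is used).
    """
    if cfg.tile_max <= 0:
        raise ValueError("deconvolve_tiled requires cfg.tile_max > 0")
    shape = tuple(image_source.shape)
    grid = plan_tiles(shape, cfg.tile_max, cfg.tile_pad)

    if scratch_dir is not None:
        os.makedirs(scratch_dir, exist_ok=True)
        acc_path = os.path.join(scratch_dir, "decon_acc.f32")
        w_path = os.path.join(scratch_dir, "decon_w.f32")
        with open(os.path.join(scratch_dir, "decon_acc.json"), "w") as fh:
            json.dump({"shape": shape, "dtype": "float32"}, fh)
        acc = np.memmap(acc_path, dtype=np.float32, mode="w+", shape=shape)
        wacc = np.memmap(w_path, dtype=np.float32, mode="w+", shape=shape)
        acc[:] = 0.0
        wacc[:] = 0.0
    else:
        acc = np.zeros(shape, dtype=np.float32)
        wacc = np.zeros(shape, dtype=np.float32)

    tile_cfg = DeconvConfig(
        n_iter=cfg.n_iter,
        method=cfg.method,
        positivity=cfg.positivity,
        background_floor_rel=cfg.background_floor_rel,
        div_guard_rel=cfg.div_guard_rel,
        support_threshold=cfg.support_threshold,
    )
    for tile in grid.tiles:
        (py0, py1), (px0, px1) = tile.padded
        sub = np.ascontiguousarray(image_source[:, py0:py1, px0:px1], dtype=np.float32)
        est, _ = shb_iterate(sub, psf, tile_cfg)
        w = blend_weights(tile, grid).astype(np.float32)
        acc[:, py0:py1, px0:px1] += est * w[None, :, :]
        wacc[:, py0:py1, px0:px1] += w[None, :, :]

    np.divide(acc, wacc, out=acc, where=wacc > 0)
    if scratch_dir is not None:
        acc.flush()
    return acc
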