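"""Comparison methods: global HE, CLAHE, and morphological enhancement.

These are re-implementations kept deliberately close to their textbook
definitions so their outputs are fully determined by the documented
conventions (CDF rounding, clip redistribution, flat disk morphology), not
by a third-party library version.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.morphology import closing as _closing
from skimage.morphology import disk
from skimage.morphology import opening as _opening

from hcha.errors import ConfigError
from hcha.imaging_io import GrayImage

__all__ = ["ClaheConfig", "StructuringElement", "hist_equalize", "clahe", "morpho_enhance"]

_N_BINS = 256


@dataclass(frozen=True)
class ClaheConfig:
    """Contextual-region grid and normalized histogram clip fraction."""

    tile_grid: tuple[int, int] = (8, 8)
    clip_limit: float = 0.01

    def __post_init__(self):
        if self.tile_grid[0] < 1 or self.tile_grid[1] < 1:
            raise ConfigError("tile_grid must be at least (1, 1)")
        if not self.clip_limit > 0:
            raise ConfigError("clip_limit must be positive")


@dataclass(frozen=True)
class StructuringElement:
    """Flat disk structuring element."""

    radius: int = 3

    def __post_init__(self):
        if self.radius < 1:
            raise ConfigError("radius must be >= 1")

    @property
    def footprint(self) -> np.ndarray:
        return disk(self.radius)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def _equalization_map(hist: np.ndarray, max_value: int) -> np.ndarray:
    """Float LUT ``v -> max_value * cdf(v)`` (CDF includes the current bin)."""
    cdf = np.cumsum(hist, dtype=np.float64)
    cdf /= cdf[-1]
    return max_value * cdf


def hist_equalize(img: GrayImage) -> GrayImage:
    """Global histogram equalization: ``v -> round(MAX * cdf(v))``.

    Rounding is half-up, so a value at CDF 0.5 maps to 128 for 8-bit data.
    The mapping is monotone, hence pixel rank order is preserved.
    """
    hist = np.bincount(img.pixels.ravel(), minlength=_N_BINS)
    lut = _round_half_up(_equalization_map(hist, img.max_value)).astype(np.uint8)
    return GrayImage(lut[img.pixels], img.max_value)


def _clipped_histogram(hist: np.ndarray, limit: float) -> np.ndarray:
    """Clip bins at ``limit`` and redistribute the excess uniformly.

    Redistribution can push bins back over the limit; iterate until the
    remaining excess is negligible, then spread it without re-clipping so
    the total count is conserved exactly.
    """
    h = hist.astype(np.float64)
    if limit >= h.sum():
        return h
    for _ in range(64):
        excess = float(np.clip(h - limit, 0, None).sum())
        if excess < 0.5:
            break
        h = np.minimum(h, limit)
        h += excess / h.size
    return h


def clahe(img: GrayImage, cfg: ClaheConfig = ClaheConfig()) -> GrayImage:
    """Contrast-limited adaptive histogram equalization.

    The image is split into ``tile_grid`` contextual regions; each region's
    histogram is clipped at ``clip_limit * region_pixel_count`` with uniform
    excess redistribution and equalized; per-pixel mappings are bilinearly
    interpolated between region centers.  With a single tile and an
    unbounded clip limit this reduces exactly to :func:`hist_equalize`.
    """
    m, n = img.shape
    tr, tc = cfg.tile_grid
    if tr > m or tc > n:
        raise ConfigError(f"tile grid {cfg.tile_grid} larger than image {img.shape}")

    row_edges = np.linspace(0, m, tr + 1).round().astype(int)
    col_edges = np.linspace(0, n, tc + 1).round().astype(int)
    centers_y = (row_edges[:-1] + row_edges[1:] - 1) / 2.0
    centers_x = (col_edges[:-1] + col_edges[1:] - 1) / 2.0

    maps = np.empty((tr, tc, _N_BINS), dtype=np.float64)
    for i in range(tr):
        for j in range(tc):
            tile = img.pixels[row_edges[i] : row_edges[i + 1], col_edges[j] : col_edges[j + 1]]
            hist = np.bincount(tile.ravel(), minlength=_N_BINS)
            limit = cfg.clip_limit * tile.size
            maps[i, j] = _equalization_map(_clipped_histogram(hist, limit), img.max_value)

    def _axis_weights(coords: np.ndarray, centers: np.ndarray):
        hi = np.searchsorted(centers, coords).clip(0, len(centers) - 1)
        lo = (hi - 1).clip(0)
        span = centers[hi] - centers[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(span > 0, (coords - centers[lo]) / np.where(span > 0, span, 1), 0.0)
        return lo, hi, np.clip(w, 0.0, 1.0)

    iy0, iy1, wy = _axis_weights(np.arange(m, dtype=np.float64), centers_y)
    ix0, ix1, wx = _axis_weights(np.arange(n, dtype=np.float64), centers_x)

    v = img.pixels
    iy0, iy1, wy = iy0[:, None], iy1[:, None], wy[:, None]
    ix0, ix1, wx = ix0[None, :], ix1[None, :], wx[None, :]
    out = (1 - wy) * ((1 - wx) * maps[iy0, ix0, v] + wx * maps[iy0, ix1, v]) + wy * (
        (1 - wx) * maps[iy1, ix0, v] + wx * maps[iy1, ix1, v]
    )
    return GrayImage(_round_half_up(out).clip(0, img.max_value), img.max_value)


def morpho_enhance(
    img: GrayImage,
    se: StructuringElement = StructuringElement(),
    mode: str = "opening",
) -> GrayImage:
    """Top-hat style contrast enhancement with a flat disk.

    ``opening`` mode amplifies bright detail: ``clip(img + (img - opening))``.
    ``closing`` mode deepens dark detail: ``clip(img - (closing - img))``.
    """
    if mode not in ("opening", "closing"):
        raise ConfigError(f"mode must be 'opening' or 'closing', got {mode!r}")
    a = img.pixels.astype(np.int64)
    fp = se.footprint
    if mode == "opening":
        out = a + (a - _opening(img.pixels, fp).astype(np.int64))
    else:
        out = a - (_closing(img.pixels, fp).astype(np.int64) - a)
    return GrayImage(out.clip(0, img.max_value), img.max_value)
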