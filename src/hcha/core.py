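"""ROI extraction, correlation-histogram construction, and block analysis.

The correlation histogram is a symmetric L x L co-occurrence matrix over the
ROI's intensity range: cell ``(a, b)`` counts ordered (centroid, neighbor)
pairs at intensities ``(a + offset, b + offset)`` across every overlapping
3 x 3 window.  The histogram plane is split into quadrant blocks (layer 1)
whose diagonal quadrants are split again (layer 2); each block back-projects
to a binary pixel mask on the ROI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from hcha.errors import DimensionError, HchaError
from hcha.imaging_io import GrayImage

__all__ = [
    "RoiWindow",
    "CorrelationHistogram",
    "Block",
    "PixelMask",
    "NEIGHBOR_OFFSETS",
    "extract_roi",
    "build_correlation_histogram",
    "partition_layer1",
    "partition_layer2",
    "project_mask",
]

#: The 8-neighborhood of a 3x3 window, as (drow, dcol) displacements.
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)


@dataclass(eq=False)
class RoiWindow:
    """A sub-image plus its origin in the parent image."""

    pixels: np.ndarray
    origin: tuple[int, int]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise DimensionError("ROI must be 2-D")

    @property
    def pixel_count(self) -> int:
        """RN: total number of ROI pixels."""
        return int(self.pixels.size)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(eq=False)
class CorrelationHistogram:
    """Square co-occurrence count matrix over the ROI intensity range.

    ``counts[a, b]`` is the number of ordered (centroid, neighbor) intensity
    pairs ``(a + offset, b + offset)``; row axis = centroid, column axis =
    neighbor.  Symmetric by construction.
    """

    counts: np.ndarray
    offset: int

    @property
    def side(self) -> int:
        """L: side length of the (square) count matrix."""
        return self.counts.shape[0]


@dataclass(frozen=True)
class Block:
    """A rectangular region of the histogram plane.

    Ranges are half-open index intervals; ``x_range`` lies on the centroid
    axis, ``y_range`` on the neighbor axis.
    """

    label: str
    x_range: tuple[int, int]
    y_range: tuple[int, int]
    layer: int

    @property
    def is_empty(self) -> bool:
        return self.x_range[0] >= self.x_range[1] or self.y_range[0] >= self.y_range[1]


@dataclass(eq=False)
class PixelMask:
    """Binary back-projection of a histogram block onto the ROI grid."""

    label: str
    mask: np.ndarray


def extract_roi(img: GrayImage, half_extent: int = 50) -> RoiWindow:
    """Extract the ``2*half_extent`` square window centred on the image.

    The window covers rows ``[cM - h, cM + h)`` and columns
    ``[cN - h, cN + h)`` with ``cM = floor(M/2)``, ``cN = floor(N/2)``.
    """
    if half_extent < 1:
        raise ValueError("half_extent must be >= 1")
    m, n = img.shape
    if m < 2 * half_extent or n < 2 * half_extent:
        raise DimensionError(
            f"image {m}x{n} too small for a {2 * half_extent}-pixel ROI"
        )
    r0 = m // 2 - half_extent
    c0 = n // 2 - half_extent
    sub = img.pixels[r0 : r0 + 2 * half_extent, c0 : c0 + 2 * half_extent]
    return RoiWindow(sub.copy(), (r0, c0))


def _neighbor_slices(shape: tuple[int, int], d: tuple[int, int]):
    """Slices selecting (centroid, neighbor) positions for displacement d."""
    m, n = shape
    dy, dx = d
    cy = slice(max(0, -dy), m - max(0, dy))
    cx = slice(max(0, -dx), n - max(0, dx))
    ny = slice(max(0, dy), m - max(0, -dy))
    nx = slice(max(0, dx), n - max(0, -dx))
    return (cy, cx), (ny, nx)


def build_correlation_histogram(roi: RoiWindow) -> CorrelationHistogram:
    """Count every in-ROI (centroid, 8-neighbor) intensity pair.

    All ROI pixels act as centroids; neighbors falling outside the ROI are
    skipped (no padding), which keeps the matrix exactly symmetric.  The
    matrix spans ``[min, max]`` of the ROI intensities, offset-indexed.
    """
    m, n = roi.shape
    if m < 2 or n < 2:
        raise DimensionError("ROI must be at least 2x2 to have 8-neighbor pairs")
    a = roi.pixels.astype(np.int64)
    lo = int(a.min())
    side = int(a.max()) - lo + 1
    counts = np.zeros((side, side), dtype=np.int64)
    for d in NEIGHBOR_OFFSETS:
        (cy, cx), (ny, nx) = _neighbor_slices((m, n), d)
        np.add.at(counts, (a[cy, cx].ravel() - lo, a[ny, nx].ravel() - lo), 1)
    return CorrelationHistogram(counts, lo)


def partition_layer1(hist: CorrelationHistogram) -> list[Block]:
    """Split the histogram plane into quadrants B1..B4 at ``m = floor(L/2)``.

    B2 is the low-intensity diagonal quadrant (object information), B4 the
    high-intensity diagonal, B1/B3 the off-diagonal (edge information)
    quadrants.  A 1x1 plane is assigned entirely to B2.
    """
    side = hist.side
    if side == 1:
        empty = (0, 0)
        return [
            Block("B1", empty, empty, 1),
            Block("B2", (0, 1), (0, 1), 1),
            Block("B3", empty, empty, 1),
            Block("B4", empty, empty, 1),
        ]
    mid = side // 2
    low, high = (0, mid), (mid, side)
    return [
        Block("B1", low, high, 1),
        Block("B2", low, low, 1),
        Block("B3", high, low, 1),
        Block("B4", high, high, 1),
    ]


def _split(rng: tuple[int, int]) -> tuple[tuple[int, int], tuple[int, int]]:
    lo, hi = rng
    mid = lo + (hi - lo) // 2
    return (lo, mid), (mid, hi)


def partition_layer2(parent: Block) -> list[Block]:
    """Split a diagonal quadrant (B2 or B4) into four sub-blocks.

    The sub-quadrant layout mirrors layer 1: for parent ``Bm``, ``Bm2`` is
    low x low, ``Bm1`` low x high, ``Bm3`` high x low, ``Bm4`` high x high.
    Odd spans split at ``floor(len/2)``; the low half gets the shorter side.
    """
    if parent.label not in ("B2", "B4"):
        raise HchaError(f"layer-2 split applies to B2/B4 only, got {parent.label}")
    (xlo, xhi) = _split(parent.x_range)
    (ylo, yhi) = _split(parent.y_range)
    p = parent.label
    return [
        Block(p + "1", xlo, yhi, 2),
        Block(p + "2", xlo, ylo, 2),
        Block(p + "3", xhi, ylo, 2),
        Block(p + "4", xhi, yhi, 2),
    ]


def project_mask(roi: RoiWindow, hist: CorrelationHistogram, block: Block) -> PixelMask:
    """Mark ROI pixels whose (value, neighbor-value) pair falls in ``block``.

    ``mask[i, j] = 1`` iff some in-ROI 8-neighbor q of pixel (i, j) yields a
    histogram coordinate ``(ROI(i,j) - offset, I(q) - offset)`` inside
    ``block.x_range x block.y_range``.  Any such coordinate has a positive
    histogram count by construction, since the pair itself contributed to it.
    """
    side = hist.side
    for lo, hi in (block.x_range, block.y_range):
        if lo < 0 or hi > side:
            raise HchaError(f"block {block.label} ranges exceed histogram plane [0, {side})")
    m, n = roi.shape
    a = roi.pixels.astype(np.int64) - hist.offset
    mask = np.zeros((m, n), dtype=np.uint8)
    if block.is_empty:
        return PixelMask(block.label, mask)
    (x0, x1), (y0, y1) = block.x_range, block.y_range
    for d in NEIGHBOR_OFFSETS:
        (cy, cx), (ny, nx) = _neighbor_slices((m, n), d)
        cen, nb = a[cy, cx], a[ny, nx]
        hit = (cen >= x0) & (cen < x1) & (nb >= y0) & (nb < y1)
        mask[cy, cx] |= hit
    return PixelMask(block.label, mask)
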