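"""Image-quality metrics: MSE, PSNR, average gradient, grand averages."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from hcha.errors import DimensionError
from hcha.imaging_io import GrayImage

__all__ = ["MetricReport", "mse", "psnr", "average_gradient", "grand_average"]


@dataclass(frozen=True)
class MetricReport:
    """Bundle of the three quality figures for one (original, enhanced) pair."""

    mse: float
    psnr: float
    avg_gradient: float


def _check_same_shape(c: GrayImage, s: GrayImage) -> None:
    if c.shape != s.shape:
        raise DimensionError(f"image shapes differ: {c.shape} vs {s.shape}")


def mse(c: GrayImage, s: GrayImage) -> float:
    """Mean squared pixel difference (signed arithmetic before squaring)."""
    _check_same_shape(c, s)
    diff = c.pixels.astype(np.float64) - s.pixels.astype(np.float64)
    return float(np.mean(diff * diff))


def psnr(c: GrayImage, s: GrayImage) -> float:
    """``10 * log10(MAX^2 / MSE)`` in dB; ``inf`` for identical images."""
    err = mse(c, s)
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(c.max_value**2 / err)


def average_gradient(s: GrayImage) -> float:
    """Mean forward-difference gradient magnitude over the (M-1)x(N-1) grid.

    Each cell contributes ``sqrt((d_row^2 + d_col^2) / 2)`` where ``d_row``
    and ``d_col`` are the forward differences in the two directions.
    """
    m, n = s.shape
    if m < 2 or n < 2:
        raise DimensionError("average gradient needs at least a 2x2 image")
    a = s.pixels.astype(np.float64)
    d_row = a[1:, :-1] - a[:-1, :-1]
    d_col = a[:-1, 1:] - a[:-1, :-1]
    return float(np.mean(np.sqrt((d_row**2 + d_col**2) / 2.0)))


def grand_average(per_group_means: Sequence[float]) -> float:
    """Unweighted arithmetic mean of per-group mean values.

    This is the aggregation used for method-versus-method summary rows:
    every group counts equally regardless of how many images it contains.
    Display rounding (2 decimals) is left to the caller.
    """
    values = list(per_group_means)
    if not values:
        raise ValueError("grand_average of an empty list")
    return float(sum(values) / len(values))
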