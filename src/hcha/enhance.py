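"""Enhancement parameters and the end-to-end pipeline.

The amplitude unit is one quarter of the ROI's population standard
deviation.  Six of the eight layer-2 sub-blocks carry signed offsets:

====== ========
block  offset
====== ========
B21    -2 gamma
B22    -1 gamma
B23     0
B24    +1 gamma
B41    +2 gamma
B42    +1 gamma
B43     0
B44    +1 gamma
====== ========

Offsets are summed over all masks containing a pixel, applied in real
arithmetic, rounded half-away-from-zero once, then clipped to the valid
intensity range.  Pixels outside every offset-bearing mask are untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from hcha.core import (
    PixelMask,
    RoiWindow,
    build_correlation_histogram,
    extract_roi,
    partition_layer1,
    partition_layer2,
    project_mask,
)
from hcha.errors import DimensionError
from hcha.imaging_io import GrayImage

__all__ = ["OFFSET_MULTIPLIERS", "EnhancementParams", "compute_params", "apply_offsets", "enhance"]

#: Signed multiple of gamma applied to each layer-2 sub-block.
OFFSET_MULTIPLIERS: dict[str, int] = {
    "B21": -2,
    "B22": -1,
    "B23": 0,
    "B24": +1,
    "B41": +2,
    "B42": +1,
    "B43": 0,
    "B44": +1,
}


@dataclass(frozen=True)
class EnhancementParams:
    """ROI statistics and the per-block offset table derived from them."""

    mu: float
    sigma: float
    gamma: float
    offset_table: dict[str, float] = field(repr=False)

    def __post_init__(self):
        assert abs(self.gamma - self.sigma / 4.0) < 1e-12


def compute_params(roi: RoiWindow) -> EnhancementParams:
    """Population mean/std of the ROI and ``gamma = sigma / 4``."""
    if roi.pixel_count < 1:
        raise DimensionError("empty ROI")
    values = roi.pixels.astype(np.float64)
    mu = float(values.mean())
    sigma = float(np.sqrt(np.mean((values - mu) ** 2)))
    gamma = sigma / 4.0
    table = {label: mult * gamma for label, mult in OFFSET_MULTIPLIERS.items()}
    return EnhancementParams(mu=mu, sigma=sigma, gamma=gamma, offset_table=table)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.where(x >= 0, np.floor(x + 0.5), np.ceil(x - 0.5))


def apply_offsets(
    roi: RoiWindow,
    masks: list[PixelMask],
    params: EnhancementParams,
    max_value: int = 255,
) -> RoiWindow:
    """Shift masked pixels by their summed offsets, round once, clip.

    Masks may overlap; contributions add.  Unknown labels default to a zero
    offset, so passing B23/B43 masks is harmless.
    """
    delta = np.zeros(roi.shape, dtype=np.float64)
    for pm in masks:
        if pm.mask.shape != roi.shape:
            raise DimensionError(
                f"mask {pm.label} shape {pm.mask.shape} != ROI shape {roi.shape}"
            )
        offset = params.offset_table.get(pm.label, 0.0)
        if offset:
            delta += offset * pm.mask
    out = _round_half_away(roi.pixels.astype(np.float64) + delta)
    out = np.clip(out, 0, max_value)
    return RoiWindow(out.astype(roi.pixels.dtype), roi.origin)


def enhance(img: GrayImage, half_extent: int = 50) -> GrayImage:
    """Full pipeline: ROI -> histogram -> blocks -> masks -> offsets -> write-back.

    Only the central ROI is modified; every pixel outside it is bit-identical
    to the input.  A zero-variance ROI makes the whole operation the identity.
    """
    roi = extract_roi(img, half_extent)
    params = compute_params(roi)
    if params.sigma == 0.0:
        return img.copy()
    hist = build_correlation_histogram(roi)
    layer1 = {b.label: b for b in partition_layer1(hist)}
    masks = []
    for parent_label in ("B2", "B4"):
        for sub in partition_layer2(layer1[parent_label]):
            if OFFSET_MULTIPLIERS[sub.label] != 0:
                masks.append(project_mask(roi, hist, sub))
    enhanced_roi = apply_offsets(roi, masks, params, max_value=img.max_value)
    out = img.pixels.copy()
    r0, c0 = roi.origin
    h, w = roi.shape
    out[r0 : r0 + h, c0 : c0 + w] = enhanced_roi.pixels
    return GrayImage(out, img.max_value)
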