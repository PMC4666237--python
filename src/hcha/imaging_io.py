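"""8-bit single-channel image I/O.

Every image entering the pipeline is normalised here to the :class:`GrayImage`
contract: a 2-D integer raster with values in ``[0, max_value]`` and
``max_value == 255``.  PNG and TIFF round-trip losslessly; single-frame
grayscale DICOM is read-only and min-max rescaled to 8 bits.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import imageio.v3 as iio

from hcha import _dicom
from hcha.errors import DimensionError, FormatError

__all__ = ["GrayImage", "read_image", "write_image"]

# ITU-R BT.601 luma weights, used for colour -> grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])

_WRITE_EXTENSIONS = {".png", ".tif", ".tiff"}
_DICOM_EXTENSIONS = {".dcm", ".dicom", ".ima"}


@dataclass(eq=False)
class GrayImage:
    """A 2-D 8-bit grayscale raster — the currency of every operation.

    Attributes
    ----------
    pixels : numpy.ndarray
        ``(M, N)`` array of ``uint8`` intensities.
    max_value : int
        Maximum representable intensity (255 for 8-bit data).
    """

    pixels: np.ndarray
    max_value: int = 255

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise DimensionError(f"expected a non-empty 2-D array, got shape {arr.shape}")
        if np.issubdtype(arr.dtype, np.floating):
            if not np.allclose(arr, np.rint(arr)):
                raise ValueError("pixel values must be integers")
            arr = np.rint(arr)
        if arr.size and (arr.min() < 0 or arr.max() > self.max_value):
            raise ValueError(
                f"pixel values outside [0, {self.max_value}]: "
                f"min={arr.min()}, max={arr.max()}"
            )
        self.pixels = arr.astype(np.uint8)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def copy(self) -> "GrayImage":
        return GrayImage(self.pixels.copy(), self.max_value)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GrayImage):
            return NotImplemented
        return self.max_value == other.max_value and np.array_equal(self.pixels, other.pixels)


def _to_gray(arr: np.ndarray) -> np.ndarray:
    """Collapse a decoded raster to a 2-D float array of gray intensities."""
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] >= 3:  # RGB / RGBA -> BT.601 luminance
            arr = arr[..., :3].astype(np.float64) @ _LUMA
        elif arr.shape[2] == 1:
            arr = arr[..., 0]
        else:  # gray + alpha
            arr = arr[..., 0]
    if arr.ndim != 2:
        raise FormatError(f"cannot interpret array of shape {arr.shape} as grayscale")
    return arr.astype(np.float64)


def _rescale_to_8bit(arr: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 255] and round to nearest integer."""
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.float64)
    return np.rint((arr - lo) * (255.0 / (hi - lo)))


def read_image(path: str | os.PathLike) -> GrayImage:
    """Read PNG, TIFF, or single-frame grayscale DICOM as a :class:`GrayImage`.

    Colour inputs are converted to BT.601 luminance and rounded.  Sources
    deeper than 8 bits (including all DICOM pixel data) are min-max rescaled
    to ``[0, 255]``.  Multi-frame DICOM raises
    :class:`~hcha.errors.UnsupportedInputError`.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    if os.path.splitext(path)[1].lower() in _DICOM_EXTENSIONS or _dicom.looks_like_dicom(path):
        arr = _dicom.read_pixel_array(path)
        return GrayImage(_rescale_to_8bit(arr.astype(np.float64)))
    try:
        raw = iio.imread(path)
    except Exception as exc:  # imageio raises a zoo of decoder errors
        raise FormatError(f"cannot decode {path!r} as an image: {exc}") from exc
    gray = np.rint(_to_gray(raw))
    if gray.max(initial=0) > 255 or gray.min(initial=0) < 0:
        gray = _rescale_to_8bit(gray)
    return GrayImage(gray)


def write_image(img: GrayImage, path: str | os.PathLike) -> None:
    """Write ``img`` as 8-bit grayscale PNG or TIFF (lossless round trip)."""
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext not in _WRITE_EXTENSIONS:
        raise FormatError(f"unsupported output extension {ext!r} (use .png/.tif/.tiff)")
    parent = os.path.dirname(path) or "."
    if not os.path.isdir(parent):
        raise IOError(f"output directory does not exist: {parent}")
    iio.imwrite(path, img.pixels)
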