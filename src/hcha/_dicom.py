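"""Minimal single-frame DICOM reader.

Supports Part-10 files (128-byte preamble + ``DICM``) carrying uncompressed
grayscale pixel data in the Implicit or Explicit VR Little Endian transfer
syntaxes.  Anything else — compressed syntaxes, multi-frame objects, colour,
undefined-length sequences — raises
:class:`~hcha.errors.UnsupportedInputError`.  Only the handful of attributes
needed to decode the raster are interpreted.
"""

from __future__ import annotations

import os
import struct

import numpy as np

from hcha.errors import FormatError, UnsupportedInputError

IMPLICIT_VR_LE = "1.2.840.10008.1.2"
EXPLICIT_VR_LE = "1.2.840.10008.1.2.1"

# VRs whose explicit encoding uses a 2-byte reserved field + 4-byte length.
_LONG_VRS = {b"OB", b"OW", b"OF", b"OD", b"OL", b"SQ", b"UC", b"UR", b"UT", b"UN"}

_TAG_ROWS = (0x0028, 0x0010)
_TAG_COLS = (0x0028, 0x0011)
_TAG_SAMPLES = (0x0028, 0x0002)
_TAG_PHOTOMETRIC = (0x0028, 0x0004)
_TAG_FRAMES = (0x0028, 0x0008)
_TAG_BITS_ALLOC = (0x0028, 0x0100)
_TAG_PIXEL_REP = (0x0028, 0x0103)
_TAG_PIXEL_DATA = (0x7FE0, 0x0010)
_TAG_TS_UID = (0x0002, 0x0010)


def looks_like_dicom(path: str | os.PathLike) -> bool:
    try:
        with open(path, "rb") as fh:
            head = fh.read(132)
    except OSError:
        return False
    return len(head) == 132 and head[128:132] == b"DICM"


def _iter_elements(buf: bytes, pos: int, explicit: bool):
    """Yield ``(tag, value_bytes, next_pos)`` for a little-endian dataset."""
    n = len(buf)
    while pos + 8 <= n:
        group, elem = struct.unpack_from("<HH", buf, pos)
        if explicit:
            vr = buf[pos + 4 : pos + 6]
            if vr in _LONG_VRS:
                (length,) = struct.unpack_from("<I", buf, pos + 8)
                body = pos + 12
            else:
                (length,) = struct.unpack_from("<H", buf, pos + 6)
                body = pos + 8
        else:
            (length,) = struct.unpack_from("<I", buf, pos + 4)
            body = pos + 8
        if length == 0xFFFFFFFF:
            raise UnsupportedInputError(
                "undefined-length DICOM element (sequence or encapsulated pixel data)"
            )
        if body + length > n:
            raise FormatError("truncated DICOM element")
        yield (group, elem), buf[body : body + length], body + length
        pos = body + length


def read_pixel_array(path: str | os.PathLike) -> np.ndarray:
    """Decode a single grayscale frame to a 2-D integer array.

    MONOCHROME1 data is inverted so that larger values are always brighter.
    No rescaling is applied here; callers map to 8 bits.
    """
    with open(path, "rb") as fh:
        buf = fh.read()
    if len(buf) < 132 or buf[128:132] != b"DICM":
        raise FormatError(f"not a Part-10 DICOM file: {path}")

    # File meta group (0002,*) is always Explicit VR Little Endian.
    pos = 132
    transfer_syntax = EXPLICIT_VR_LE
    for tag, value, nxt in _iter_elements(buf, pos, explicit=True):
        if tag[0] != 0x0002:
            break
        if tag == _TAG_TS_UID:
            transfer_syntax = value.decode("ascii").rstrip("\x00 ")
        pos = nxt

    if transfer_syntax == EXPLICIT_VR_LE:
        explicit = True
    elif transfer_syntax == IMPLICIT_VR_LE:
        explicit = False
    else:
        raise UnsupportedInputError(f"unsupported transfer syntax: {transfer_syntax}")

    attrs: dict[tuple[int, int], bytes] = {}
    for tag, value, nxt in _iter_elements(buf, pos, explicit=explicit):
        attrs[tag] = value
        if tag == _TAG_PIXEL_DATA:
            break

    def _us(tag, default=None):
        if tag not in attrs:
            if default is None:
                raise FormatError(f"missing required DICOM attribute {tag}")
            return default
        return struct.unpack("<H", attrs[tag][:2])[0]

    samples = _us(_TAG_SAMPLES, 1)
    if samples != 1:
        raise UnsupportedInputError(f"only single-sample grayscale supported, got {samples}")
    frames = int(attrs.get(_TAG_FRAMES, b"1").decode("ascii").strip() or "1")
    if frames != 1:
        raise UnsupportedInputError(f"multi-frame DICOM ({frames} frames) not supported")
    photometric = attrs.get(_TAG_PHOTOMETRIC, b"MONOCHROME2").decode("ascii").strip("\x00 ")
    if not photometric.startswith("MONOCHROME"):
        raise UnsupportedInputError(f"unsupported photometric interpretation: {photometric}")

    rows, cols = _us(_TAG_ROWS), _us(_TAG_COLS)
    bits = _us(_TAG_BITS_ALLOC, 16)
    signed = _us(_TAG_PIXEL_REP, 0) == 1
    if bits == 8:
        dtype = np.int8 if signed else np.uint8
    elif bits == 16:
        dtype = np.int16 if signed else np.uint16
    else:
        raise UnsupportedInputError(f"unsupported BitsAllocated: {bits}")

    if _TAG_PIXEL_DATA not in attrs:
        raise FormatError("DICOM file has no pixel data")
    raw = attrs[_TAG_PIXEL_DATA]
    needed = rows * cols * (bits // 8)
    if len(raw) < needed:
        raise FormatError("pixel data shorter than Rows*Columns")
    arr = np.frombuffer(raw[:needed], dtype=dtype).reshape(rows, cols).astype(np.int64)
    if photometric == "MONOCHROME1":  # min is white; flip to brighter-is-larger
        arr = int(arr.max()) + int(arr.min()) - arr
    return arr
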