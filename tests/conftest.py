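import struct
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from hcha.imaging_io import GrayImage
from hcha.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom42():
    """Default 256x256 phantom at seed 42, with its label mask."""
    return generate_phantom(PhantomSpec(seed=42))


@pytest.fixture
def random_image(rng):
    return GrayImage(rng.integers(0, 256, (64, 64)))


def write_minimal_dicom(
    path,
    array,
    *,
    bits=16,
    photometric="MONOCHROME2",
    n_frames=1,
    explicit=True,
    signed=False,
):
    """Encode a tiny Part-10 DICOM file (little endian) for reader tests."""
    array = np.asarray(array)
    rows, cols = array.shape[-2:]

    def _pad(value: bytes, pad: bytes = b"\x00") -> bytes:
        return value + pad if len(value) % 2 else value

    def element(group, elem, vr, value: bytes) -> bytes:
        value = _pad(value, b" " if vr in (b"CS", b"IS") else b"\x00")
        if explicit:
            if vr in (b"OB", b"OW", b"UN", b"SQ", b"UT"):
                return struct.pack("<HH2sHI", group, elem, vr, 0, len(value)) + value
            return struct.pack("<HH2sH", group, elem, vr, len(value)) + value
        return struct.pack("<HHI", group, elem, len(value)) + value

    def meta_element(group, elem, vr, value: bytes) -> bytes:
        value = _pad(value)
        return struct.pack("<HH2sH", group, elem, vr, len(value)) + value

    ts = b"1.2.840.10008.1.2.1" if explicit else b"1.2.840.10008.1.2"
    body = b"".join(
        [
            element(0x0028, 0x0002, b"US", struct.pack("<H", 1)),
            element(0x0028, 0x0004, b"CS", photometric.encode()),
            element(0x0028, 0x0008, b"IS", str(n_frames).encode()),
            element(0x0028, 0x0010, b"US", struct.pack("<H", rows)),
            element(0x0028, 0x0011, b"US", struct.pack("<H", cols)),
            element(0x0028, 0x0100, b"US", struct.pack("<H", bits)),
            element(0x0028, 0x0103, b"US", struct.pack("<H", 1 if signed else 0)),
            element(
                0x7FE0,
                0x0010,
                b"OW",
                array.astype(
                    {8: (np.int8 if signed else np.uint8), 16: (np.int16 if signed else np.uint16)}[
                        bits
                    ]
                ).tobytes(),
            ),
        ]
    )
    blob = b"\x00" * 128 + b"DICM" + meta_element(0x0002, 0x0010, b"UI", ts) + body
    Path(path).write_bytes(blob)
    return path
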