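"""Seedable synthetic brain-slice phantoms with ground-truth label masks.

A phantom is a dark background, an elliptical "brain" made of an outer
bright tissue band and an inner darker band, and small paired elliptical
sub-structures at distinct gray levels, all placed so the fixed central
analysis window contains every structure.  Gaussian noise is added, then the
image is rounded and clipped to 8 bits.

Label codes: 0 background, 1 outer tissue band, 2 inner tissue band,
3 + k for the k-th structure in the spec.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

from hcha.errors import PhantomSpecError
from hcha.imaging_io import GrayImage

__all__ = [
    "StructureSpec",
    "PhantomSpec",
    "default_structures",
    "generate_phantom",
    "parse_spec_file",
    "LABEL_BACKGROUND",
    "LABEL_OUTER_TISSUE",
    "LABEL_INNER_TISSUE",
    "FIRST_STRUCTURE_LABEL",
]

LABEL_BACKGROUND = 0
LABEL_OUTER_TISSUE = 1
LABEL_INNER_TISSUE = 2
FIRST_STRUCTURE_LABEL = 3


@dataclass(frozen=True)
class StructureSpec:
    """One elliptical sub-structure, centred relative to the image center."""

    name: str
    center_offset: tuple[int, int]  # (drow, dcol) from the image center
    semi_axes: tuple[float, float]  # (row, col) semi-axes in pixels
    intensity: int


def default_structures() -> list[StructureSpec]:
    """Three bilateral structure pairs inside the central 100x100 window."""
    return [
        StructureSpec("caudate_left", (-10, -20), (8, 5), 60),
        StructureSpec("caudate_right", (-10, 20), (8, 5), 60),
        StructureSpec("putamen_left", (5, -25), (10, 6), 80),
        StructureSpec("putamen_right", (5, 25), (10, 6), 80),
        StructureSpec("thalamus_left", (22, -16), (9, 7), 140),
        StructureSpec("thalamus_right", (22, 16), (9, 7), 140),
    ]


@dataclass(frozen=True)
class PhantomSpec:
    size: tuple[int, int] = (256, 256)
    background_level: int = 10
    tissue_levels: tuple[int, int] = (170, 110)  # (outer band, inner band)
    brain_axes: tuple[float, float] = (100, 110)  # outer ellipse semi-axes
    inner_axes: tuple[float, float] = (75, 88)  # inner band semi-axes
    structures: tuple[StructureSpec, ...] = field(
        default_factory=lambda: tuple(default_structures())
    )
    noise_sd: float = 5.0
    seed: int = 0


def _ellipse_mask(
    shape: tuple[int, int], center: tuple[float, float], axes: tuple[float, float]
) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return ((yy - center[0]) / axes[0]) ** 2 + ((xx - center[1]) / axes[1]) ** 2 <= 1.0


def _validate(spec: PhantomSpec, brain: np.ndarray, structure_masks: list[np.ndarray]) -> None:
    levels = (spec.background_level, *spec.tissue_levels) + tuple(
        s.intensity for s in spec.structures
    )
    for lv in levels:
        if not 0 <= lv <= 255:
            raise PhantomSpecError(f"intensity {lv} outside [0, 255]")
    if spec.noise_sd < 0:
        raise PhantomSpecError("noise_sd must be non-negative")
    for s, m in zip(spec.structures, structure_masks):
        if not m.any():
            raise PhantomSpecError(f"structure {s.name!r} rasterizes to zero pixels")
        if (m & ~brain).any():
            raise PhantomSpecError(f"structure {s.name!r} extends outside the brain ellipse")


def generate_phantom(spec: PhantomSpec = PhantomSpec()) -> tuple[GrayImage, np.ndarray]:
    """Render the phantom and its integer label mask.

    Identical specs (including seed) produce bit-identical outputs.  With
    ``noise_sd = 0`` every pixel equals its region's specified intensity.
    """
    m, n = spec.size
    center = (m // 2, n // 2)
    brain = _ellipse_mask((m, n), center, spec.brain_axes)
    inner = _ellipse_mask((m, n), center, spec.inner_axes) & brain
    structure_masks = [
        _ellipse_mask(
            (m, n),
            (center[0] + s.center_offset[0], center[1] + s.center_offset[1]),
            s.semi_axes,
        )
        for s in spec.structures
    ]
    _validate(spec, brain, structure_masks)

    image = np.full((m, n), float(spec.background_level))
    labels = np.full((m, n), LABEL_BACKGROUND, dtype=np.int32)
    image[brain] = spec.tissue_levels[0]
    labels[brain] = LABEL_OUTER_TISSUE
    image[inner] = spec.tissue_levels[1]
    labels[inner] = LABEL_INNER_TISSUE
    for k, (s, mask) in enumerate(zip(spec.structures, structure_masks)):
        image[mask] = s.intensity
        labels[mask] = FIRST_STRUCTURE_LABEL + k

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        image = image + rng.normal(0.0, spec.noise_sd, size=(m, n))
    pixels = np.clip(np.rint(image), 0, 255)
    return GrayImage(pixels), labels


def parse_spec_file(path: str | os.PathLike) -> PhantomSpec:
    """Read a plain-text ``key = value`` phantom description.

    Recognised keys: ``size``, ``background_level``, ``tissue_levels``,
    ``brain_axes``, ``inner_axes``, ``noise_sd``, ``seed``, and repeatable
    ``structure = name drow dcol semi_row semi_col intensity`` lines.
    Omitted keys keep their defaults; any ``structure`` line replaces the
    default structure set.
    """
    spec = PhantomSpec()
    structures: list[StructureSpec] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise PhantomSpecError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            parts = value.split()
            try:
                if key == "size":
                    spec = replace(spec, size=(int(parts[0]), int(parts[1])))
                elif key == "background_level":
                    spec = replace(spec, background_level=int(parts[0]))
                elif key == "tissue_levels":
                    spec = replace(spec, tissue_levels=(int(parts[0]), int(parts[1])))
                elif key == "brain_axes":
                    spec = replace(spec, brain_axes=(float(parts[0]), float(parts[1])))
                elif key == "inner_axes":
                    spec = replace(spec, inner_axes=(float(parts[0]), float(parts[1])))
                elif key == "noise_sd":
                    spec = replace(spec, noise_sd=float(parts[0]))
                elif key == "seed":
                    spec = replace(spec, seed=int(parts[0]))
                elif key == "structure":
                    structures.append(
                        StructureSpec(
                            name=parts[0],
                            center_offset=(int(parts[1]), int(parts[2])),
                            semi_axes=(float(parts[3]), float(parts[4])),
                            intensity=int(parts[5]),
                        )
                    )
                else:
                    raise PhantomSpecError(f"{path}:{lineno}: unknown key {key!r}")
            except (IndexError, ValueError) as exc:
                raise PhantomSpecError(f"{path}:{lineno}: bad value for {key!r}: {exc}") from exc
    if structures:
        spec = replace(spec, structures=tuple(structures))
    return spec
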