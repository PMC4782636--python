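"""Core image types and pixel-level operations.

A fluoroscopic frame is modelled as an additive attenuation map: every
structure the beam traverses *adds* intensity, so a frame is the element-wise
sum of a tumor component and a background component.  All structure motion is
treated as an integer-pixel 2-D translation.

Conventions
-----------
Arrays are indexed ``[row, col]`` with 0-based indices; a :class:`Displacement`
``(u, v)`` moves content by ``u`` pixels along +x (columns) and ``v`` pixels
along +y (rows), i.e. the shifted image reads the source at ``(x - u, y - v)``.
Pixels whose source location falls outside the frame are tracked with an
explicit validity mask rather than silently zero-padded, so that reference
updates never ingest data that left the field of view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IntensityImage",
    "Displacement",
    "Region",
    "EmptyImageError",
    "LostTargetError",
    "shift_image",
    "binarize",
    "center_of_mass",
    "add_images",
]


class EmptyImageError(ValueError):
    """Raised when an operation needs at least one valid pixel and has none."""


class LostTargetError(RuntimeError):
    """Raised when the tracked target vanishes (empty binarization / region)."""


@dataclass(frozen=True)
class Displacement:
    """Integer pixel translation; ``u`` along +x (columns), ``v`` along +y (rows)."""

    u: int
    v: int

    def __add__(self, other: "Displacement") -> "Displacement":
        return Displacement(self.u + other.u, self.v + other.v)

    def __sub__(self, other: "Displacement") -> "Displacement":
        return Displacement(self.u - other.u, self.v - other.v)

    def __neg__(self) -> "Displacement":
        return Displacement(-self.u, -self.v)

    def as_tuple(self) -> tuple[int, int]:
        return (self.u, self.v)


@dataclass
class IntensityImage:
    """An m x n grid of non-negative additive attenuation intensities.

    Parameters
    ----------
    values : ndarray, shape (m, n)
        Pixel intensities in arbitrary attenuation units.
    valid : ndarray of bool, shape (m, n), optional
        True where the value is defined.  Defaults to all-true.
    spacing_mm : float
        Isotropic pixel pitch in millimetres.
    """

    values: np.ndarray
    valid: np.ndarray | None = None
    spacing_mm: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("values must be a non-empty 2-D array")
        if self.valid is None:
            self.valid = np.ones(self.values.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.values.shape:
                raise ValueError("valid mask shape must match values")
        if not (self.spacing_mm > 0):
            raise ValueError("spacing_mm must be positive")
        if not np.all(np.isfinite(self.values[self.valid])):
            raise ValueError("values must be finite wherever valid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "IntensityImage":
        return IntensityImage(self.values.copy(), self.valid.copy(), self.spacing_mm)


@dataclass
class Region:
    """A boolean pixel set, e.g. the region inside an initial tumor outline."""

    mask: np.ndarray = field()

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def shift_image(img: IntensityImage, d: Displacement) -> IntensityImage:
    """Translate ``img`` by ``d`` integer pixels: output(x, y) = img(x-u, y-v).

    Destination pixels whose source is out of bounds (or invalid) get value 0
    and ``valid=False``.  Shape and spacing are preserved.
    """
    m, n = img.shape
    u, v = int(d.u), int(d.v)
    out_vals = np.zeros((m, n), dtype=np.float64)
    out_valid = np.zeros((m, n), dtype=bool)
    # destination window rows [max(v,0), m+min(v,0)) maps to source rows shifted by -v
    r0, r1 = max(v, 0), m + min(v, 0)
    c0, c1 = max(u, 0), n + min(u, 0)
    if r1 > r0 and c1 > c0:
        src = img.values[r0 - v : r1 - v, c0 - u : c1 - u]
        srcm = img.valid[r0 - v : r1 - v, c0 - u : c1 - u]
        out_vals[r0:r1, c0:c1] = np.where(srcm, src, 0.0)
        out_valid[r0:r1, c0:c1] = srcm
    return IntensityImage(out_vals, out_valid, img.spacing_mm)


def binarize(img: IntensityImage, rel_threshold: float) -> Region:
    """Threshold at ``rel_threshold`` times the maximum valid intensity.

    The mask is true where ``value >= rel_threshold * max``; if the maximum is
    not positive the mask is all-false.
    """
    if not 0.0 < rel_threshold < 1.0:
        raise ValueError("rel_threshold must lie in (0, 1)")
    if not img.valid.any():
        raise EmptyImageError("binarize: image has no valid pixels")
    vmax = float(img.values[img.valid].max())
    if vmax <= 0.0:
        return Region(np.zeros(img.shape, dtype=bool))
    return Region(img.valid & (img.values >= rel_threshold * vmax))


def center_of_mass(region: Region) -> tuple[float, float]:
    """Unweighted centroid ``(x_c, y_c)`` of the true pixels, sub-pixel precision."""
    rows, cols = np.nonzero(region.mask)
    if rows.size == 0:
        raise LostTargetError("center_of_mass: empty region (target lost)")
    return float(cols.mean()), float(rows.mean())


def add_images(a: IntensityImage, b: IntensityImage) -> IntensityImage:
    """Element-wise superimposition; a pixel is valid only if valid in both."""
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not np.isclose(a.spacing_mm, b.spacing_mm):
        raise ValueError("spacing mismatch")
    valid = a.valid & b.valid
    vals = np.where(valid, a.values + b.values, 0.0)
    return IntensityImage(vals, valid, a.spacing_mm)
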