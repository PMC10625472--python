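"""Shared data types and unit conventions.

Coordinate convention used throughout the package: image row = +y, image
column = +x, origin at the center of pixel ``[0, 0]``.  All physical
coordinates and displacements are in micrometres (µm), elastic moduli and
traction stresses in pascal (Pa).  Integrated forces are in Pa·µm², which is
exactly one piconewton (1 Pa·µm² = 1e-12 N); nanonewton values are pN/1000.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GridImage",
    "GelSubstrate",
    "Point2D",
    "to_physical",
    "to_pixel",
    "PN_PER_PA_UM2",
    "NN_PER_PA_UM2",
]

# 1 Pa·µm² = 1e-12 N = 1 pN
PN_PER_PA_UM2 = 1.0
NN_PER_PA_UM2 = 1e-3


@dataclass(frozen=True)
class Point2D:
    """A point on the gel surface, µm, in the row=+y / col=+x frame."""

    x: float
    y: float

    def to_pixel(self, pixel_size_um: float) -> tuple[float, float]:
        """Return fractional (row, col) pixel indices."""
        return self.y / pixel_size_um, self.x / pixel_size_um


@dataclass(frozen=True)
class GelSubstrate:
    """Linear-elastic gel substrate parameters.

    Parameters
    ----------
    young_modulus_Pa:
        Young's modulus E of the gel, Pa. Polyacrylamide TFM substrates are
        typically in the 1–30 kPa range.
    poisson_ratio:
        Poisson ratio ν. The reduced Green tensor used by the traction
        solver is only valid for an incompressible substrate (ν = 0.5,
        appropriate for hydrogels, which are mostly water); the solver
        rejects ν < 0.5.
    """

    young_modulus_Pa: float
    poisson_ratio: float = 0.5

    def __post_init__(self) -> None:
        if not (self.young_modulus_Pa > 0):
            raise ValueError(f"Young's modulus must be > 0 Pa, got {self.young_modulus_Pa}")
        if not (0.0 <= self.poisson_ratio <= 0.5):
            raise ValueError(f"Poisson ratio must be in [0, 0.5], got {self.poisson_ratio}")


@dataclass
class GridImage:
    """A single 2D intensity image on a regular pixel grid.

    Intensities are kept as floating point regardless of the source bit
    depth; focus metrics and correlation need full precision.
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel_tag: str = ""
    t_index: int | None = None
    z_index: int | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"image must be 2D, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 8 or self.pixels.shape[1] < 8:
            raise ValueError(f"image must be at least 8x8 pixels, got {self.pixels.shape}")
        if not (self.pixel_size_um > 0):
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image intensities must be finite (no NaN/Inf)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def copy(self) -> "GridImage":
        return GridImage(
            self.pixels.copy(),
            self.pixel_size_um,
            channel_tag=self.channel_tag,
            t_index=self.t_index,
            z_index=self.z_index,
        )


def to_physical(row: int, col: int, pixel_size_um: float, shape: tuple[int, int] | None = None) -> Point2D:
    """Convert integer pixel indices to a physical point (µm).

    ``x = col * pixel_size_um`` and ``y = row * pixel_size_um``; the origin
    is the center of pixel [0, 0]. When ``shape`` is given, out-of-bounds
    indices are rejected.
    """
    if shape is not None:
        nr, nc = shape
        if not (0 <= row < nr and 0 <= col < nc):
            raise IndexError(f"pixel index ({row}, {col}) out of bounds for image of shape {shape}")
    return Point2D(x=col * pixel_size_um, y=row * pixel_size_um)


def to_pixel(point: Point2D, pixel_size_um: float) -> tuple[float, float]:
    """Convert a physical point to fractional (row, col) pixel indices."""
    return point.y / pixel_size_um, point.x / pixel_size_um
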