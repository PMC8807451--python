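"""In-memory container for axial CT image data in Hounsfield units.

The package works in physical units throughout: pixel spacing and slice
thickness are millimetres, pixel values are HU.  The coordinate convention is
x to the right, y downward, with the physical origin at the *centre* of the
image unless an explicit origin offset is given.  All estimators consume and
return :class:`ImageGrid` objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = ["ImageGrid"]


@dataclass
class ImageGrid:
    """A 2D axial slice or 3D stack of CT numbers.

    Parameters
    ----------
    pixels
        ``(ny, nx)`` or ``(nz, ny, nx)`` array of CT numbers in HU.
    pixel_spacing
        In-plane pixel pitch in mm (isotropic).
    slice_thickness
        Reconstructed slice thickness in mm.
    origin
        Physical ``(x, y)`` position, in mm, of the image centre.  With the
        default ``(0, 0)`` the body axis of a centred phantom is at (0, 0).
    meta
        Free-form provenance (seeds, simulation parameters, source files).
    """

    pixels: np.ndarray
    pixel_spacing: float
    slice_thickness: float = 0.5
    origin: tuple[float, float] = (0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim not in (2, 3):
            raise ValueError(f"pixels must be 2D or 3D, got ndim={self.pixels.ndim}")
        if not self.pixel_spacing > 0:
            raise ValueError(f"pixel_spacing must be > 0, got {self.pixel_spacing}")
        if not self.slice_thickness > 0:
            raise ValueError(
                f"slice_thickness must be > 0, got {self.slice_thickness}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")

    # -- geometry ---------------------------------------------------------

    @property
    def nx(self) -> int:
        return self.pixels.shape[-1]

    @property
    def ny(self) -> int:
        return self.pixels.shape[-2]

    @property
    def n_slices(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[0]

    def x_coords(self) -> np.ndarray:
        """Physical x (mm) of every pixel-centre column."""
        return self.origin[0] + (np.arange(self.nx) - (self.nx - 1) / 2) * self.pixel_spacing

    def y_coords(self) -> np.ndarray:
        """Physical y (mm) of every pixel-centre row."""
        return self.origin[1] + (np.arange(self.ny) - (self.ny - 1) / 2) * self.pixel_spacing

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid ``(X, Y)`` of pixel-centre coordinates in mm."""
        return np.meshgrid(self.x_coords(), self.y_coords())

    def extent(self) -> tuple[float, float, float, float]:
        """``(xmin, xmax, ymin, ymax)`` of the pixel-centre lattice in mm."""
        x = self.x_coords()
        y = self.y_coords()
        return float(x[0]), float(x[-1]), float(y[0]), float(y[-1])

    # -- slicing ----------------------------------------------------------

    def slice2d(self, k: int = 0) -> np.ndarray:
        """Return slice ``k`` as a 2D array (a 2D grid has only slice 0)."""
        if self.pixels.ndim == 2:
            if k != 0:
                raise IndexError("2D grid has a single slice (index 0)")
            return self.pixels
        return self.pixels[k]

    def iter_slices(self) -> Iterator[np.ndarray]:
        for k in range(self.n_slices):
            yield self.slice2d(k)

    def with_pixels(self, pixels: np.ndarray, **meta) -> "ImageGrid":
        """Copy of this grid with new pixel data and updated metadata."""
        merged = dict(self.meta)
        merged.update(meta)
        return ImageGrid(
            pixels=pixels,
            pixel_spacing=self.pixel_spacing,
            slice_thickness=self.slice_thickness,
            origin=self.origin,
            meta=merged,
        )
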