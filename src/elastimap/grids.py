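"""Basic 2D grid containers shared by the registration and mapping code.

Conventions
-----------
* Images are 2D arrays indexed ``[row, col]``; ``y`` is the row axis and
  ``x`` the column axis, pixel-centred, 0-based.
* Displacement fields are stored as ``(H, W, 2)`` arrays in **pixel** units,
  component 0 along the row axis, component 1 along the column axis.
  The deformation is ``phi(x) = x + u(x)``.
* Physical spacing (mm) is metadata only: the numerical core works in pixel
  units and spacing is applied at I/O time.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ScalarImage2D", "DisplacementField", "as_pixels", "as_field"]


@dataclass
class ScalarImage2D:
    """A 2D pixel grid with physical spacing.

    Parameters
    ----------
    pixels : ndarray, shape (H, W)
        Intensity values (arbitrary units). Must be finite.
    spacing : (float, float)
        Pixel size ``(dy, dx)`` in mm along the row/column axes.
    """

    pixels: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 2:
            raise ValueError("image must be 2D with shape >= 2x2")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image values must be finite")
        if len(self.spacing) != 2 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class DisplacementField:
    """Per-pixel displacement ``u`` in pixel units, shape ``(H, W, 2)``."""

    u: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 3 or self.u.shape[-1] != 2:
            raise ValueError("displacement field must have shape (H, W, 2)")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("displacement components must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape[:2]


def as_pixels(image) -> np.ndarray:
    """Return the pixel array of an image given as array or ScalarImage2D."""
    if isinstance(image, ScalarImage2D):
        return image.pixels
    a = np.asarray(image, dtype=float)
    if a.ndim != 2:
        raise ValueError("expected a 2D image")
    return a


def as_field(u) -> np.ndarray:
    """Return the ``(H, W, 2)`` array of a displacement field."""
    if isinstance(u, DisplacementField):
        return u.u
    a = np.asarray(u, dtype=float)
    if a.ndim != 3 or a.shape[-1] != 2:
        raise ValueError("expected a displacement field of shape (H, W, 2)")
    return a
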