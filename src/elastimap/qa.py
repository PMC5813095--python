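"""Deformation-field quality assessment maps.

Two independent views of a displacement field ``u`` (deformation
``phi(x) = x + u(x)``):

* the local deformation field (LDF) map: a checkerboard sampled through
  ``phi`` — straight lines wherever the field is a pure translation,
  bowed/compressed grids where it is not;
* the local volume change (LVC) map: ``det(grad phi) - 1`` per pixel,
  zero for volume preservation, positive for expansion, negative for
  compression (through-plane motion is not considered).

Both are typically overlaid with an isocontour of the native T1 map for
anatomical orientation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from matplotlib.colors import Normalize
from skimage import measure

from .grids import as_field, as_pixels

__all__ = ["LvcMap", "ldf_map", "lvc_map", "isocontour_overlay", "colorize"]


@dataclass
class LvcMap:
    """Per-pixel local volume change ``det(grad phi) - 1``.

    ``border_mask`` flags pixels where the 3x3 central-difference stencil
    is undefined and one-sided differences were used instead.
    """

    values: np.ndarray
    border_mask: np.ndarray


def ldf_map(u, checker_period: int = 8) -> np.ndarray:
    """Checkerboard image sampled through the deformation.

    ``LDF(x) = C(phi(x))`` with ``C`` a binary checkerboard of the given
    period (px).  Evaluated analytically at the warped positions, so a
    translation shifts the board without bending any line.
    """
    if checker_period < 2:
        raise ValueError("checker period must be at least 2 px")
    uu = as_field(u)
    h, w = uu.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    py = np.floor((yy + uu[..., 0]) / checker_period)
    px = np.floor((xx + uu[..., 1]) / checker_period)
    return np.mod(py + px, 2.0)


def lvc_map(u) -> LvcMap:
    """Local volume change ``det(I + grad u) - 1``.

    Spatial derivatives are central differences over the 3x3 pixel
    neighbourhood (one-sided at the image border, flagged in
    ``border_mask``).  Exactly zero for constant (translation) fields.
    """
    uu = as_field(u)
    if min(uu.shape[:2]) < 3:
        raise ValueError("field must be at least 3x3 for the Jacobian stencil")
    d0u0, d1u0 = np.gradient(uu[..., 0])
    d0u1, d1u1 = np.gradient(uu[..., 1])
    det = (1.0 + d0u0) * (1.0 + d1u1) - d1u0 * d0u1
    border = np.zeros(uu.shape[:2], dtype=bool)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    return LvcMap(values=det - 1.0, border_mask=border)


def colorize(image, window=None, cmap: str = "gray") -> np.ndarray:
    """Map a scalar image to RGB with a fixed window (deterministic)."""
    a = as_pixels(image)
    if window is None:
        finite = a[np.isfinite(a)]
        window = (float(finite.min()), float(finite.max())) if finite.size else (0.0, 1.0)
    if window[1] <= window[0]:
        window = (window[0], window[0] + 1.0)
    norm = Normalize(vmin=window[0], vmax=window[1], clip=True)
    rgba = colormaps[cmap](norm(np.nan_to_num(a, nan=window[0])))
    return rgba[..., :3]


def isocontour_overlay(
    map_image,
    reference,
    level: float,
    window=None,
    cmap: str = "RdBu",
    contour_color=(0.0, 0.0, 0.0),
) -> np.ndarray:
    """Draw the isocontour of ``reference`` at ``level`` over a colormapped
    rendering of ``map_image``.  Returns an RGB array."""
    base = colorize(map_image, window=window, cmap=cmap)
    ref = as_pixels(reference)
    if ref.shape != base.shape[:2]:
        raise ValueError("reference and map shapes differ")
    for contour in measure.find_contours(ref, level):
        rr = np.clip(np.round(contour[:, 0]).astype(int), 0, ref.shape[0] - 1)
        cc = np.clip(np.round(contour[:, 1]).astype(int), 0, ref.shape[1] - 1)
        base[rr, cc] = contour_color
    return base
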