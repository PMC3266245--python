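"""Tip-shape morphological dilation and erosion of height maps.

An AFM image is, geometrically, the trajectory of the tip apex as the tip
surface touches the sample: the grayscale (max-plus) dilation of the
sample height map by the reflected tip. This module implements that
operator for parametric spherical/paraboloidal tips so model surfaces
(e.g. a structural-biology-derived height map) can be dilated before
comparison with scan output.

The tip profile is apex-referenced (apex at height 0, the rest of the tip
below), so dilating a flat plane returns the same level. Dilation and
erosion use the same structuring function and form an adjunction, giving
the usual opening identities; ``scipy.ndimage`` provides the max/min-plus
kernels and the test suite holds them to an exact brute-force oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import grey_dilation, grey_erosion

SPHERE = "sphere"
PARABOLOID = "paraboloid"


@dataclass(frozen=True)
class TipSurface:
    """Axisymmetric tip: apex ``radius`` (nm) and lateral truncation.

    ``support_radius`` limits the structuring-element footprint; it is
    enlarged automatically (with a warning) when the height range of the
    map being dilated needs a wider tip shoulder.
    """

    kind: str = SPHERE
    radius: float = 2.0
    support_radius: float = 0.0   # 0 -> derived from the map height range

    def __post_init__(self):
        if self.kind not in (SPHERE, PARABOLOID):
            raise ValueError(f"unknown tip kind {self.kind!r}")
        if not self.radius > 0:
            raise ValueError("tip radius must be > 0")

    def drop(self, r):
        """Vertical distance below the apex at lateral offset r (>= 0)."""
        r = np.asarray(r, dtype=float)
        if self.kind == PARABOLOID:
            return r**2 / (2.0 * self.radius)
        inside = r <= self.radius
        d = np.where(inside,
                     self.radius - np.sqrt(np.maximum(
                         self.radius**2 - np.minimum(r, self.radius)**2, 0.0)),
                     np.inf)
        return d

    def required_support(self, height_range: float) -> float:
        """Lateral reach needed so the tip shoulder can touch features
        across ``height_range`` of relief."""
        if self.kind == PARABOLOID:
            return float(np.sqrt(2.0 * self.radius * max(height_range, 0.0)))
        return self.radius  # beyond the hemisphere the side wall is vertical

    def structure(self, pixel_size: float, height_range: float):
        """Structuring function on the pixel grid: apex 0, negative below.

        Returns a (2m+1, 2m+1) array of -drop values; -inf marks pixels
        outside the support (they can never make contact).
        """
        need = self.required_support(height_range)
        support = self.support_radius
        if support and support < need:
            warnings.warn(
                f"tip support radius {support} nm too small for a height "
                f"range of {height_range} nm; enlarged to {need} nm",
                stacklevel=2)
            support = need
        if not support:
            support = need
        m = int(np.floor(support / pixel_size))
        off = np.arange(-m, m + 1) * pixel_size
        rr = np.hypot(off[:, None], off[None, :])
        s = -self.drop(rr)
        s[rr > support] = -np.inf
        s[m, m] = 0.0
        return s


def dilate(height: np.ndarray, tip: TipSurface, pixel_size: float = 1.0,
           boundary: str = "reflect") -> np.ndarray:
    """Grayscale dilation of a height map by the tip (the imaged surface).

    ``out(x) = max_u [ height(x - u) + tip_profile(u) ]`` with the apex at
    zero, so the output is everywhere >= the input. ``boundary`` is
    ``"reflect"`` (default; avoids edge dips on particle-centered maps) or
    ``"shrink"`` (-inf padding: only real data can support the tip).
    """
    height = np.asarray(height, dtype=float)
    s = tip.structure(pixel_size, float(height.max() - height.min())
                      if height.size else 0.0)
    finite = np.isfinite(s)
    footprint = finite
    structure = np.where(finite, s, 0.0)
    if boundary == "reflect":
        mode, cval = "reflect", 0.0
    elif boundary == "shrink":
        mode, cval = "constant", -np.inf
    else:
        raise ValueError(f"unknown boundary mode {boundary!r}")
    return grey_dilation(height, footprint=footprint, structure=structure,
                         mode=mode, cval=cval)


def erode(height: np.ndarray, tip: TipSurface, pixel_size: float = 1.0,
          boundary: str = "reflect") -> np.ndarray:
    """Min-plus adjoint of :func:`dilate` (surface reconstruction step).

    ``erode(dilate(h))`` is the morphological opening by the tip: the best
    estimate of the sample surface recoverable from its image, with
    ``dilate(erode(d)) <= d`` and idempotence on dilated inputs.
    """
    height = np.asarray(height, dtype=float)
    s = tip.structure(pixel_size, float(height.max() - height.min())
                      if height.size else 0.0)
    finite = np.isfinite(s)
    structure = np.where(finite, s, 0.0)
    if boundary == "reflect":
        mode, cval = "reflect", 0.0
    elif boundary == "shrink":
        mode, cval = "constant", np.inf
    else:
        raise ValueError(f"unknown boundary mode {boundary!r}")
    return grey_erosion(height, footprint=finite, structure=structure,
                        mode=mode, cval=cval)


def brute_force_dilate(height: np.ndarray, tip: TipSurface,
                       pixel_size: float = 1.0) -> np.ndarray:
    """O(N^2 * support) max-plus convolution with reflect padding.

    Reference implementation used as the exactness oracle for
    :func:`dilate`; keep for verification, not for large maps.
    """
    height = np.asarray(height, dtype=float)
    s = tip.structure(pixel_size, float(height.max() - height.min())
                      if height.size else 0.0)
    m = s.shape[0] // 2
    padded = np.pad(height, m, mode="reflect")
    ny, nx = height.shape
    out = np.full((ny, nx), -np.inf)
    for di in range(-m, m + 1):
        for dj in range(-m, m + 1):
            add = s[m + di, m + dj]
            if not np.isfinite(add):
                continue
            shifted = padded[m - di:m - di + ny, m - dj:m - dj + nx]
            out = np.maximum(out, shifted + add)
    return out
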