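"""CIELAB colour representation and the Euclidean colour metrics.

Every decision rule in the two-stage tongue-colour classifier lives in
CIELAB (L* in [0, 100], a* green-red, b* blue-yellow).  Input tongue
images arrive as 24-bit sRGB after segmentation and coating removal,
with non-tongue pixels set to exact black (0, 0, 0).  Exact black is
treated as a reserved background sentinel: it maps to Lab (0, 0, 0)
exactly, so that "distance from the black pixel" means the same thing
in both colour spaces, and it defines the foreground mask.

Conversion uses sRGB companding with the D65 reference white and the 2
degree standard observer (the sRGB defaults).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color as _skcolor

__all__ = [
    "LabImage",
    "rgb_to_lab",
    "lab_to_rgb",
    "color_distance",
    "centroid_distance",
    "BLACK",
]

#: The Lab coordinates of the reserved background colour.
BLACK = np.zeros(3)


@dataclass(frozen=True)
class LabImage:
    """A tongue image in CIELAB with its foreground (tongue-pixel) mask.

    Attributes
    ----------
    lab:
        ``(H, W, 3)`` float array of (L*, a*, b*) values.  Background
        pixels are exactly ``(0, 0, 0)``.
    foreground_mask:
        ``(H, W)`` boolean array, ``True`` where the source pixel was a
        tongue pixel (any RGB channel nonzero).
    """

    lab: np.ndarray
    foreground_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.lab.ndim != 3 or self.lab.shape[-1] != 3:
            raise ValueError(f"lab must be (H, W, 3), got {self.lab.shape}")
        if self.foreground_mask.shape != self.lab.shape[:2]:
            raise ValueError(
                "foreground_mask shape "
                f"{self.foreground_mask.shape} != image shape {self.lab.shape[:2]}"
            )

    @property
    def height(self) -> int:
        return self.lab.shape[0]

    @property
    def width(self) -> int:
        return self.lab.shape[1]

    @property
    def pixels(self) -> np.ndarray:
        """All pixels flattened to ``(H*W, 3)`` in row-major order."""
        return self.lab.reshape(-1, 3)

    def foreground_pixels(self) -> np.ndarray:
        """Lab values of tongue pixels only, ``(n_fg, 3)``."""
        return self.lab[self.foreground_mask]


def rgb_to_lab(rgb: np.ndarray) -> LabImage:
    """Convert a 24-bit sRGB image to a :class:`LabImage`.

    Exact-black input pixels are forced to Lab ``(0, 0, 0)`` and marked
    as background rather than being passed through the converter (the
    converter would give them L* = 0 but the forcing makes the identity
    exact and robust to floating-point noise).

    Parameters
    ----------
    rgb:
        ``(H, W, 3)`` array of integer channel values in [0, 255].

    Raises
    ------
    ValueError
        If the input is not a 3-channel image or channels fall outside
        [0, 255].
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {rgb.shape}")
    if rgb.min() < 0 or rgb.max() > 255:
        raise ValueError("RGB channels must lie in [0, 255]")
    mask = np.any(rgb != 0, axis=-1)
    lab = _skcolor.rgb2lab(rgb.astype(np.float64) / 255.0)
    lab[~mask] = 0.0
    return LabImage(lab=lab, foreground_mask=mask)


def lab_to_rgb(lab: np.ndarray) -> np.ndarray:
    """Convert Lab values back to 8-bit sRGB (gamut-clipped).

    Used by the synthetic generator; the round trip through 8-bit
    quantisation is exact to within +/- 1 channel unit for in-gamut
    colours.
    """
    lab = np.asarray(lab, dtype=np.float64)
    rgb = _skcolor.lab2rgb(lab)
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)


def color_distance(p: np.ndarray, q: np.ndarray) -> np.ndarray | float:
    """Euclidean distance between two Lab colours.

    ``sqrt((L2-L1)^2 + (a2-a1)^2 + (b2-b1)^2)`` — the plain Euclidean
    metric used throughout (no perceptual weighting).  Broadcasts over
    leading axes, so it accepts single pixels or whole pixel arrays.
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    d = np.sqrt(np.sum((q - p) ** 2, axis=-1))
    return float(d) if d.ndim == 0 else d


def centroid_distance(p: np.ndarray, centroid: np.ndarray) -> np.ndarray | float:
    """Distance of a pixel from a cluster centroid (C1*, C2*, C3*).

    The k-means assignment metric; identical to :func:`color_distance`
    evaluated at the centroid point, and kept as a separate name because
    the two distances play different roles (assignment vs. the
    distance-from-black identifier).
    """
    return color_distance(p, centroid)
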