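"""Foreground/background segmentation by local adaptive thresholding.

Root cross-section micrographs rarely have a uniform background: staining
intensity drifts across the slide, so a single global threshold (e.g.
Otsu) misclassifies whole regions.  Instead each pixel is compared with
the mean intensity of the square window centred on it; pixels deviating
by more than ``T`` from their local mean are wall/foreground.  The cell
walls of a stained section are dark lines on a brighter background, so by
default the test is applied to the negated image (``polarity =
"dark_walls"``).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["mean_filter", "difference_image", "local_threshold"]


def _check_half_width(w: int) -> int:
    w = int(w)
    if w < 1:
        raise ValueError(f"window half-width must be >= 1, got {w}")
    return w


def mean_filter(image: np.ndarray, w: int) -> np.ndarray:
    """Mean of the ``(2w+1) x (2w+1)`` window centred on each pixel.

    Near the image border the window is truncated to its overlap with
    the image and normalised by the actual pixel count, which avoids a
    spurious band of foreground along the border.
    """
    w = _check_half_width(w)
    image = np.asarray(image, dtype=np.float64)
    size = 2 * w + 1
    # Sum over the truncated window divided by its true pixel count;
    # constant-padding with 0 makes uniform_filter return exactly that sum.
    window_sum = ndimage.uniform_filter(image, size=size, mode="constant", cval=0.0) * size**2
    counts = ndimage.uniform_filter(
        np.ones_like(image), size=size, mode="constant", cval=0.0
    ) * size**2
    return window_sum / np.round(counts)


def difference_image(image: np.ndarray, w: int) -> np.ndarray:
    """Deviation of each pixel from its local window mean, ``I - I*M``."""
    image = np.asarray(image, dtype=np.float64)
    return image - mean_filter(image, w)


def local_threshold(
    image: np.ndarray, T: float, w: int, polarity: str = "dark_walls"
) -> np.ndarray:
    """Binary foreground mask from the local-threshold rule.

    With ``polarity="bright_walls"`` a pixel is foreground when its
    difference-image value strictly exceeds ``T``; with the default
    ``"dark_walls"`` the image is negated first, which is equivalent to
    testing for a deviation below ``-T``.
    """
    if not 0.0 < T < 1.0:
        raise ValueError(f"threshold T must lie in (0, 1), got {T}")
    diff = difference_image(image, w)
    if polarity == "dark_walls":
        return diff < -T
    if polarity == "bright_walls":
        return diff > T
    raise ValueError(f"unknown polarity {polarity!r}")
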