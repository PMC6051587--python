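"""Locate the ganglion corner and rotate it to the image origin.

Quarter-field crops place the explant's soma mass at one corner of the image.
The soma mass is by far the most brightly stained structure, so the corner
whose neighbourhood has the highest mean intensity identifies it.  The image
is then rotated by a multiple of 90 degrees so the ganglion sits at the
top-left pixel, coordinate (0, 0) — the origin from which all radial
distances are measured (x rightward, y downward).
"""

from __future__ import annotations

import numpy as np

__all__ = ["CORNERS", "detect_ganglion_corner", "orient_to_origin", "corner_rotation_k"]

#: fixed order; also the tie-break priority for corner detection.
CORNERS = ("top-left", "top-right", "bottom-right", "bottom-left")

# number of counterclockwise quarter turns (np.rot90 k) mapping each corner
# to top-left.
_ROT_K = {"top-left": 0, "top-right": 1, "bottom-right": 2, "bottom-left": 3}


def corner_rotation_k(corner: str) -> int:
    """Counterclockwise quarter turns that bring ``corner`` to top-left."""
    try:
        return _ROT_K[corner]
    except KeyError:
        raise ValueError(f"corner must be one of {CORNERS}, got {corner!r}") from None


def _corner_windows(shape: tuple[int, int], window_frac: float):
    rows, cols = shape
    side = max(1, round(window_frac * min(rows, cols)))
    return {
        "top-left": (slice(0, side), slice(0, side)),
        "top-right": (slice(0, side), slice(cols - side, cols)),
        "bottom-right": (slice(rows - side, rows), slice(cols - side, cols)),
        "bottom-left": (slice(rows - side, rows), slice(0, side)),
    }


def detect_ganglion_corner(image: np.ndarray, window_frac: float = 0.25) -> str:
    """Return the corner with the brightest corner-anchored square window.

    The window side is ``round(window_frac * min(height, width))`` pixels
    (at least 1).  A window rather than a single pixel makes the detection
    robust to hot pixels while still being dominated by the soma mass.  Ties
    resolve in the fixed order top-left, top-right, bottom-left, bottom-right.
    """
    image = np.asarray(image)
    if image.ndim != 2 or min(image.shape) < 2:
        raise ValueError(f"image must be 2D and at least 2x2, got shape {image.shape}")
    if not 0.0 < window_frac <= 0.5:
        raise ValueError(f"window_frac must be in (0, 0.5], got {window_frac!r}")
    windows = _corner_windows(image.shape, window_frac)
    tie_order = ("top-left", "top-right", "bottom-left", "bottom-right")
    means = [float(np.mean(image[windows[c]], dtype=np.float64)) for c in tie_order]
    return tie_order[int(np.argmax(means))]


def orient_to_origin(image: np.ndarray, corner: str) -> np.ndarray:
    """Rotate by the 90-degree multiple that maps ``corner`` to top-left.

    The rotation permutes pixels: the value multiset is preserved exactly, so
    any statistic of the whole image (e.g. the adaptive threshold) is
    unchanged.  ``corner="top-left"`` returns the input unrotated.
    """
    k = corner_rotation_k(corner)
    image = np.asarray(image)
    if k == 0:
        return image
    return np.ascontiguousarray(np.rot90(image, k))
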