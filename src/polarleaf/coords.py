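"""Frame conventions and the single pixel↔leaf conversion point.

Pixel frame: 0-based (row, col), x rightward (col), y downward (row).
Leaf frame: micrometres, mathematical orientation (y upward), so angle
arithmetic (counterclockwise positive) works unmodified.  The y-flip
between the two frames happens here and nowhere else.
"""

from __future__ import annotations

import numpy as np


def pixel_to_leaf(points_rc, n_rows: int, pixel_size: float) -> np.ndarray:
    """Map pixel (row, col) point(s) to leaf-frame (x, y) in μm."""
    pts = np.atleast_2d(np.asarray(points_rc, dtype=float))
    x = pts[:, 1] * pixel_size
    y = (n_rows - 1 - pts[:, 0]) * pixel_size
    out = np.column_stack([x, y])
    return out[0] if np.asarray(points_rc).ndim == 1 else out


def leaf_to_pixel(points_xy, n_rows: int, pixel_size: float) -> np.ndarray:
    """Inverse of :func:`pixel_to_leaf` (returns float (row, col))."""
    pts = np.atleast_2d(np.asarray(points_xy, dtype=float))
    col = pts[:, 0] / pixel_size
    row = (n_rows - 1) - pts[:, 1] / pixel_size
    out = np.column_stack([row, col])
    return out[0] if np.asarray(points_xy).ndim == 1 else out
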