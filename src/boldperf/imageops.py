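"""Small shared image operations: integer translation and normalized
cross-correlation.  Translations use the array (row, col) convention with
0-based indices; shifted-in pixels are zero-filled, shifted-out pixels are
dropped."""
from __future__ import annotations

import numpy as np


def shift_image(img: np.ndarray, shift: tuple[int, int]) -> np.ndarray:
    """Translate a 2D array by integer (drow, dcol) with zero fill.

    A positive ``drow`` moves content toward larger row indices (down),
    a positive ``dcol`` toward larger column indices (right).
    """
    dr, dc = int(shift[0]), int(shift[1])
    out = np.zeros_like(img)
    nr, nc = img.shape
    if abs(dr) >= nr or abs(dc) >= nc:
        return out
    src_r = slice(max(0, -dr), min(nr, nr - dr))
    src_c = slice(max(0, -dc), min(nc, nc - dc))
    dst_r = slice(max(0, dr), min(nr, nr + dr))
    dst_c = slice(max(0, dc), min(nc, nc + dc))
    out[dst_r, dst_c] = img[src_r, src_c]
    return out


def normalized_cross_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two same-shaped images (0 if either is flat)."""
    x = np.asarray(a, dtype=float).ravel()
    y = np.asarray(b, dtype=float).ravel()
    x = x - x.mean()
    y = y - y.mean()
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        return 0.0
    return float(np.dot(x, y) / (nx * ny))
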