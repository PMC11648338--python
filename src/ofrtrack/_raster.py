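"""Anti-aliased coverage rasterization shared by the renderer and the
pupil-boundary model.

Edge pixels take area-weighted intermediate values: the fraction of the
pixel square covered by the shape, estimated by regular sub-sampling
(``subsample`` x ``subsample`` points per pixel).  Pixel centers sit at
integer coordinates, so pixel (i, j) covers [i-0.5, i+0.5] x [j-0.5, j+0.5].
"""

from __future__ import annotations

import numpy as np


def _subgrid(x0: int, n: int, subsample: int) -> np.ndarray:
    """Sub-sample x-coordinates for pixels x0..x0+n-1, shape (n*subsample,)."""
    off = (np.arange(subsample) + 0.5) / subsample - 0.5
    return (x0 + np.arange(n))[:, None] + off[None, :]


def ellipse_coverage(x0: int, y0: int, w: int, h: int,
                     cx: float, cy: float, a: float, b: float,
                     theta: float = 0.0, subsample: int = 8) -> np.ndarray:
    """Per-pixel covered-area fraction of a filled rotated ellipse.

    The window spans pixels (x0..x0+w-1, y0..y0+h-1) of the parent frame;
    the returned array has shape (h, w) with values in [0, 1].
    """
    xs = _subgrid(x0, w, subsample).ravel()
    ys = _subgrid(y0, h, subsample).ravel()
    dx = xs[None, :] - cx
    dy = ys[:, None] - cy
    if theta != 0.0:
        c, s = np.cos(theta), np.sin(theta)
        u = dx * c + dy * s
        v = -dx * s + dy * c
    else:
        u, v = np.broadcast_arrays(dx, dy)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return inside.reshape(h, subsample, w, subsample).mean(axis=(1, 3))


def disk_coverage(x0: int, y0: int, w: int, h: int,
                  cx: float, cy: float, r: float,
                  subsample: int = 8) -> np.ndarray:
    return ellipse_coverage(x0, y0, w, h, cx, cy, r, r, 0.0, subsample)


def halfplane_coverage_above(y0: int, h: int, y_edge: float) -> np.ndarray:
    """Fraction of each pixel row lying above (smaller y than) ``y_edge``.

    Exact for an axis-aligned edge; shape (h, 1) for broadcasting over a
    window of ``h`` rows starting at ``y0``.
    """
    ys = y0 + np.arange(h, dtype=float)
    return np.clip(y_edge - (ys - 0.5), 0.0, 1.0)[:, None]
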