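"""Subpixel head-marker displacement between two frames.

The head marker is a high-contrast dark circle; across the ~80 ms between
frames the head moves by at most a few tens of micrometres, i.e. about a
pixel, and the motion is treated as pure translation.  The estimate is
built in two stages:

1. *Whole pixels*: each marker ROI is shrunk to the tight rectangle around
   the thresholded dark blob; after verifying the two rectangles have the
   same size, the difference of their corners gives the integer
   displacement.
2. *Subpixel fraction*: Pearson correlation between the rectangle's
   interior in frame A and the nine same-sized regions within one pixel of
   the aligned rectangle in frame B gives a 3x3 correlation grid; the
   coefficients are Fisher r-to-z transformed and the peak of the z surface
   is located with subpixel resolution.

The two parts are added to give the full signed displacement in pixels.

Peak localization note: a piecewise-bilinear interpolant of the 3x3 *grid
of correlation values* always attains its maximum at one of the nine nodes
(it is linear along each axis within a cell), so interpolating the grid
cannot place a peak between pixels.  The bilinear interpolation is
therefore applied where it is meaningful — to the *image*: the correlation
is evaluated at fractional shifts of the bilinearly interpolated frame-B
patch.  Because a bilinearly shifted patch is a fixed linear combination
of the four surrounding integer-shift patches, the Pearson correlation at
any fractional shift has a closed form in precomputed patch moments, and
the Fisher-z surface can be searched densely (coarse-to-fine, final step
0.001 px) at negligible cost, with ties broken toward the smaller shift.
A closed-form separable paraboloid fit to the 3x3 z grid ("quadratic") is
available behind a flag for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import (MarkerLostError, SizeMismatchError,
                     UndefinedCorrelationError)
from .io import Displacement2D, Frame, ROIBox, crop

__all__ = [
    "TightRect",
    "CorrelationGrid",
    "shrink_to_marker",
    "integer_displacement",
    "correlation_grid",
    "subpixel_refine",
    "marker_displacement",
]

_R_CLIP = 1.0 - 1e-12


@dataclass
class TightRect:
    """Minimal axis-aligned rectangle around the thresholded dark blob,
    in parent-frame coordinates; records the threshold used."""

    x0: int
    y0: int
    w: int
    h: int
    threshold_used: float

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError("tight rectangle must have positive size")

    @property
    def corner(self) -> np.ndarray:
        return np.array([self.x0, self.y0])


@dataclass
class CorrelationGrid:
    """3x3 Pearson correlations (and their Fisher z transforms) at the
    integer shifts (-1, 0, +1) squared; the grid center is zero shift."""

    r: np.ndarray
    z: np.ndarray
    offsets: tuple[int, ...] = (-1, 0, 1)


def shrink_to_marker(frame: Frame, roi: ROIBox,
                     min_contrast: float = 10.0) -> TightRect:
    """Shrink a marker ROI to the tight rectangle around the dark blob.

    Threshold: midpoint between the ROI's 5th and 95th intensity
    percentiles — robust because the marker is high-contrast by design.
    The largest connected below-threshold component is taken as the marker.
    """
    roi.validate_within(frame)
    patch = crop(frame, roi).astype_float()
    p5, p95 = np.percentile(patch, [5, 95])
    if p95 - p5 < min_contrast:
        raise MarkerLostError(f"ROI contrast {p95 - p5:.1f} below "
                              f"{min_contrast} counts")
    thresh = 0.5 * (p5 + p95)
    # median prefilter: keeps the blob edge in place but stops single noisy
    # pixels at the extremes from jittering the rectangle bounds
    mask = ndimage.median_filter(patch, size=3) < thresh
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        raise MarkerLostError("no below-threshold pixels in marker ROI")
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    blob = labels == areas.argmax()
    x0, y0, w, h = tight_bbox(blob)
    return TightRect(x0=roi.x0 + x0, y0=roi.y0 + y0, w=w, h=h,
                     threshold_used=float(thresh))


def tight_bbox(blob: np.ndarray, min_thickness: int = 3
               ) -> tuple[int, int, int, int]:
    """(x0, y0, w, h) of the blob, ignoring rows/columns thinner than
    ``min_thickness`` pixels.

    A round blob's true extreme column still contains a chord of many
    pixels, whereas noise-flipped protrusions are one or two pixels thick;
    trimming thin rows/columns makes the rectangle bounds reproducible
    across frames.  Translation equivariance is preserved exactly.
    """
    col_counts = blob.sum(axis=0)
    row_counts = blob.sum(axis=1)
    cols = np.nonzero(col_counts >= min_thickness)[0]
    rows = np.nonzero(row_counts >= min_thickness)[0]
    if cols.size == 0 or rows.size == 0:  # tiny blob: fall back to raw bbox
        ys, xs = np.nonzero(blob)
        cols = np.array([xs.min(), xs.max()])
        rows = np.array([ys.min(), ys.max()])
    return (int(cols.min()), int(rows.min()),
            int(cols.max() - cols.min() + 1),
            int(rows.max() - rows.min() + 1))


def integer_displacement(a: TightRect, b: TightRect,
                         size_tol: int = 2) -> np.ndarray:
    """Whole-pixel displacement from rectangle corners.

    The rectangles must match in size to within ``size_tol`` pixels on each
    axis; a larger mismatch indicates blur or partial occlusion and signals
    trial discard.
    """
    if abs(a.w - b.w) > size_tol or abs(a.h - b.h) > size_tol:
        raise SizeMismatchError(
            f"tight rectangles differ in size: {a.w}x{a.h} vs {b.w}x{b.h} "
            f"(tol {size_tol})")
    return b.corner - a.corner


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        raise UndefinedCorrelationError("zero-variance correlation patch")
    return float((a * b).sum() / denom)


def correlation_grid(patch_a: np.ndarray,
                     patch_b_context: np.ndarray) -> CorrelationGrid:
    """Pearson correlations of patch A against the nine one-pixel shifts of
    the aligned region in frame B, with Fisher r-to-z applied."""
    patch_a = np.asarray(patch_a, dtype=float)
    ctx = np.asarray(patch_b_context, dtype=float)
    h, w = patch_a.shape
    if ctx.shape[0] != h + 2 or ctx.shape[1] != w + 2:
        raise ValueError("context must extend the patch by exactly 1 px "
                         "on all sides")
    r = np.empty((3, 3))
    for iy, dy in enumerate((-1, 0, 1)):
        for ix, dx in enumerate((-1, 0, 1)):
            sub = ctx[1 + dy:1 + dy + h, 1 + dx:1 + dx + w]
            r[iy, ix] = _pearson(patch_a, sub)
    z = np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))
    return CorrelationGrid(r=r, z=z)


class _CorrSurface:
    """Closed-form Pearson correlation of patch A against the bilinearly
    interpolated frame-B patch at any fractional shift in [-1, +1]^2.

    A bilinear shift by (dx, dy) inside the cell with integer corner
    (ix, iy) is the weighted sum of the four corner patches, so every
    first- and second-order moment needed for the correlation is a fixed
    combination of the 9x9 patch Gram matrix, computed once.
    """

    def __init__(self, patch_a: np.ndarray, ctx: np.ndarray) -> None:
        h, w = patch_a.shape
        stack = np.stack([ctx[1 + dy:1 + dy + h, 1 + dx:1 + dx + w].ravel()
                          for dy in (-1, 0, 1) for dx in (-1, 0, 1)])
        a = patch_a.ravel()
        self.n = a.size
        self.sa = a.sum()
        var_a = float(a @ a) - self.sa ** 2 / self.n
        if var_a <= 0:
            raise UndefinedCorrelationError("zero-variance correlation patch")
        self.var_a = var_a
        self.s1 = stack.sum(axis=1)          # (9,)
        self.sab = stack @ a                 # (9,)
        self.gram = stack @ stack.T          # (9, 9)
        # Bilinear interpolation averages sensor noise, shrinking the
        # shifted patch's variance at fractional offsets; left uncorrected
        # this inflates the correlation toward half-pixel shifts.  The
        # z_grid denominator therefore adds back the suppressed noise
        # variance, using a wavelet-based robust noise estimate.
        from skimage.restoration import estimate_sigma
        self.noise_var = float(estimate_sigma(ctx)) ** 2

    @staticmethod
    def _corner_idx(ix: int, iy: int) -> list[int]:
        # patch index for integer shift (dx, dy) is (dy+1)*3 + (dx+1)
        return [(iy + 1 + j) * 3 + (ix + 1 + i)
                for j in (0, 1) for i in (0, 1)]

    def z_grid(self, dxs: np.ndarray, dys: np.ndarray) -> np.ndarray:
        """Fisher-z of the correlation on the grid dys x dxs (all shifts
        must lie within one bilinear cell)."""
        ix = int(np.floor(min(dxs.min(), 1.0 - 1e-9)))
        iy = int(np.floor(min(dys.min(), 1.0 - 1e-9)))
        idx = self._corner_idx(ix, iy)
        fx = (dxs - ix)[None, :]
        fy = (dys - iy)[:, None]
        wts = [(1 - fx) * (1 - fy), fx * (1 - fy), (1 - fx) * fy, fx * fy]
        sx = sum(w * self.s1[i] for w, i in zip(wts, idx))
        sax = sum(w * self.sab[i] for w, i in zip(wts, idx))
        sxx = sum(wi * wj * self.gram[i, j]
                  for wi, i in zip(wts, idx) for wj, j in zip(wts, idx))
        var_x = sxx - sx ** 2 / self.n
        sum_w2 = sum(w * w for w in wts)
        var_x = var_x + self.n * self.noise_var * (1.0 - sum_w2)
        cov = sax - self.sa * sx / self.n
        with np.errstate(invalid="ignore", divide="ignore"):
            r = cov / np.sqrt(self.var_a * var_x)
        r = np.where(var_x > 0, r, -1.0)
        return np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))


def _argmax_tie_center(z: np.ndarray, dxs: np.ndarray,
                       dys: np.ndarray) -> np.ndarray:
    vmax = z.max()
    iy, ix = np.nonzero(z >= vmax - 1e-12)
    cand = np.column_stack([dxs[ix], dys[iy]])
    return cand[np.argmin(np.hypot(cand[:, 0], cand[:, 1]))]


def _dense_peak(patch_a: np.ndarray, ctx: np.ndarray) -> np.ndarray:
    """Dense coarse-to-fine argmax (final step 0.001 px) of the Fisher-z
    correlation surface, ties broken toward the smaller |shift|."""
    surf = _CorrSurface(patch_a, ctx)
    lim = 1.0 - 1e-3
    best = None
    best_val = -np.inf
    # coarse pass, one bilinear cell at a time (step 0.01)
    for ix in (-1, 0):
        dxs = np.clip(ix + np.arange(0.0, 1.0001, 0.01), -lim, lim)
        for iy in (-1, 0):
            dys = np.clip(iy + np.arange(0.0, 1.0001, 0.01), -lim, lim)
            z = surf.z_grid(dxs, dys)
            cand = _argmax_tie_center(z, dxs, dys)
            val = z.max()
            if val > best_val + 1e-12 or (
                    abs(val - best_val) <= 1e-12 and best is not None
                    and np.hypot(*cand) < np.hypot(*best)):
                best_val, best = val, cand
    # fine pass within the winning cell
    cx, cy = best
    qx = min(int(np.floor(min(cx, 1 - 1e-9))), 0)
    qy = min(int(np.floor(min(cy, 1 - 1e-9))), 0)
    dxs = np.clip(cx + np.arange(-0.015, 0.0151, 0.001), max(-lim, qx),
                  min(lim, qx + 1))
    dys = np.clip(cy + np.arange(-0.015, 0.0151, 0.001), max(-lim, qy),
                  min(lim, qy + 1))
    dxs, dys = np.unique(dxs), np.unique(dys)
    z = surf.z_grid(dxs, dys)
    return _argmax_tie_center(z, dxs, dys)


def _parabolic_peak(z: np.ndarray) -> np.ndarray:
    """Closed-form separable paraboloid peak through the center cross."""

    def axis_peak(zm: float, z0: float, zp: float) -> float:
        denom = zm - 2.0 * z0 + zp
        if denom >= 0:  # flat or valley: no interior maximum
            return 0.0
        return float(np.clip(0.5 * (zm - zp) / denom, -0.999, 0.999))

    return np.array([axis_peak(z[1, 0], z[1, 1], z[1, 2]),
                     axis_peak(z[0, 1], z[1, 1], z[2, 1])])


def subpixel_refine(patch_a: np.ndarray, patch_b_context: np.ndarray,
                    method: str = "dense") -> np.ndarray:
    """Subpixel fraction of the displacement, strictly inside (-1, +1)^2.

    ``method``: "dense" (default; dense argmax of the Fisher-z surface of
    the bilinearly interpolated correlation) or "quadratic" (closed-form
    paraboloid fit to the 3x3 z grid).
    """
    patch_a = np.asarray(patch_a, dtype=float)
    ctx = np.asarray(patch_b_context, dtype=float)
    if method == "dense":
        return _dense_peak(patch_a, ctx)
    if method == "quadratic":
        return _parabolic_peak(correlation_grid(patch_a, ctx).z)
    raise ValueError(f"unknown peak method {method!r}")


def _one_way_displacement(frame_a: Frame, frame_b: Frame,
                          rect_a: TightRect, rect_b: TightRect,
                          size_tol: int, method: str) -> np.ndarray:
    whole = integer_displacement(rect_a, rect_b, size_tol=size_tol)

    # Use a common rectangle size so the correlation patches align even
    # when the tight rectangles differ by up to size_tol.
    w = min(rect_a.w, rect_b.w)
    h = min(rect_a.h, rect_b.h)
    a_img = frame_a.astype_float()
    b_img = frame_b.astype_float()
    ax0, ay0 = rect_a.x0, rect_a.y0
    if (ay0 < 0 or ax0 < 0 or ay0 + h > frame_a.height
            or ax0 + w > frame_a.width):
        raise MarkerLostError("marker rectangle touches the frame border")
    patch_a = a_img[ay0:ay0 + h, ax0:ax0 + w]

    # Thresholded rectangle corners can be off by one pixel relative to the
    # true whole-pixel displacement, which would leave the correlation peak
    # on the border of the 3x3 grid where interpolation is unreliable.  If
    # the grid maximum is not the center, re-anchor the window on it (the
    # whole-pixel estimate absorbs the shift) and rebuild the grid, so the
    # subpixel fraction is always interpolated around an interior peak.
    bx0, by0 = rect_b.x0, rect_b.y0
    for _ in range(3):
        if (by0 - 1 < 0 or bx0 - 1 < 0 or by0 + h + 1 > frame_b.height
                or bx0 + w + 1 > frame_b.width):
            raise MarkerLostError("marker context exceeds the frame border")
        ctx_b = b_img[by0 - 1:by0 + h + 1, bx0 - 1:bx0 + w + 1]
        grid = correlation_grid(patch_a, ctx_b)
        iy, ix = np.unravel_index(np.argmax(grid.z), (3, 3))
        if (iy, ix) == (1, 1):
            break
        bx0 += ix - 1
        by0 += iy - 1
        whole = whole + np.array([ix - 1, iy - 1])
    frac = subpixel_refine(patch_a, ctx_b, method=method)
    return whole + frac


def marker_displacement(frame_a: Frame, frame_b: Frame,
                        roi_a: ROIBox, roi_b: ROIBox,
                        size_tol: int = 2,
                        method: str = "dense") -> Displacement2D:
    """Full signed head-marker displacement A -> B in pixels.

    Integer stage from tight-rectangle corners plus the subpixel
    correlation-peak refinement, evaluated in both directions and
    antisymmetrized (the mean of the forward estimate and the negated
    reverse estimate).  Symmetrization guarantees
    ``disp(A, B) == -disp(B, A)`` exactly and averages away what remains of
    the one-sided interpolation bias.  Raises a discard signal
    (:class:`~ofrtrack.errors.TrackingError`) when the marker is lost, the
    rectangles mismatch, or the correlation is undefined.
    """
    rect_a = shrink_to_marker(frame_a, roi_a)
    rect_b = shrink_to_marker(frame_b, roi_b)
    fwd = _one_way_displacement(frame_a, frame_b, rect_a, rect_b,
                                size_tol, method)
    rev = _one_way_displacement(frame_b, frame_a, rect_b, rect_a,
                                size_tol, method)
    est = 0.5 * (fwd - rev)
    return Displacement2D(float(est[0]), float(est[1]),
                          frame_pair=(frame_a.frame_id, frame_b.frame_id))
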