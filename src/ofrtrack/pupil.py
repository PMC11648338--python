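"""Subpixel pupil-center extraction.

The marker's rectangle-plus-correlation trick cannot be reused for the
pupil: pupil size and shape fluctuate continuously (diameter SD of about
0.21 px even within 80 ms), so correlating two frames would confound size
change with displacement.  Instead the pupil *center* is extracted
independently in every frame:

1. the detected pupil ROI is shrunk to a tight rectangle around the dark
   region (corneal-reflection pixels are masked first);
2. a small bank of elliptical templates (various sizes and aspect ratios)
   locates the center with pixel-level resolution — only the few templates
   near the rectangle's size need to be tried;
3. an anti-aliased dark-ellipse-on-light model, whose edge pixels take
   area-weighted intermediate values, is fit by continuous local
   optimization of (cx, cy, a, b, theta), with the semi-axes constrained to
   within one pixel of the template stage.

Center displacement between frames is then a difference of two fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtr
from skimage import measure
from skimage.feature import match_template

from .detect import DetectionParams, detect_pupil_region, is_absent
from .errors import LowConfidenceError, NoMatchError, PupilLostError
from .io import Frame, ROIBox, crop
from .marker import TightRect, tight_bbox

__all__ = [
    "PupilFit",
    "FilterBank",
    "shrink_to_pupil",
    "match_filter_bank",
    "refine_annulus",
    "pupil_center",
    "pupil_diameter_change",
]


@dataclass
class PupilFit:
    """Subpixel ellipse fit to the pupil.

    ``(cx, cy)`` are in the coordinates of whatever raster the fit was run
    on; :func:`pupil_center` maps them back to full-frame coordinates.
    ``stage`` records whether the fit stopped at the pixel-level template
    stage or went through the anti-aliased annulus refinement.
    """

    cx: float
    cy: float
    a: float
    b: float
    theta: float = 0.0
    score: float = 0.0
    stage: str = "filter_bank"
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise ValueError("semi-axes must satisfy a >= b > 0")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")

    @property
    def center(self) -> np.ndarray:
        return np.array([self.cx, self.cy])

    @property
    def mean_diameter(self) -> float:
        return self.a + self.b


@dataclass
class FilterBank:
    """Elliptical template bank for the pixel-level stage."""

    radii: tuple[float, ...] = tuple(np.arange(8.0, 61.0, 2.0))
    aspect_ratios: tuple[float, ...] = (1.0, 0.95, 0.9, 0.85)
    score_min: float = 0.5

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii) or list(self.radii) != sorted(self.radii):
            raise ValueError("radii must be positive and ascending")
        if any(not 0 < ar <= 1 for ar in self.aspect_ratios):
            raise ValueError("aspect ratios must lie in (0, 1]")


def shrink_to_pupil(eye_patch: Frame, pupil_roi: ROIBox,
                    bright_quantile: float = 0.99,
                    min_contrast: float = 10.0) -> TightRect:
    """Tight dark-region rectangle around the pupil, in eye-patch coords.

    Corneal reflections are bright outliers; pixels above the
    ``bright_quantile`` of the whole eye patch are masked before the
    percentile threshold is computed, so a reflection overlapping the pupil
    edge does not distort the rectangle.
    """
    pupil_roi.validate_within(eye_patch)
    img = eye_patch.astype_float()
    bright_thresh = np.quantile(img, bright_quantile)
    patch = img[pupil_roi.y0:pupil_roi.y0 + pupil_roi.h,
                pupil_roi.x0:pupil_roi.x0 + pupil_roi.w]
    valid = patch < bright_thresh
    if valid.sum() < 16:
        raise PupilLostError("pupil ROI saturated by reflections")
    p5, p95 = np.percentile(patch[valid], [5, 95])
    if p95 - p5 < min_contrast:
        raise PupilLostError("no dark pupil region in ROI")
    thresh = 0.5 * (p5 + p95)
    from scipy import ndimage
    mask = (ndimage.median_filter(patch, size=3) < thresh) & valid
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        raise PupilLostError("no below-threshold pupil pixels")
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    x0, y0, w, h = tight_bbox(labels == areas.argmax())
    return TightRect(x0=pupil_roi.x0 + x0, y0=pupil_roi.y0 + y0, w=w, h=h,
                     threshold_used=float(thresh))


# ---------------------------------------------------------------------------
# stage 1: template bank


def _ellipse_template(a: float, b: float, subsample: int = 4) -> np.ndarray:
    from . import _raster
    half = int(math.ceil(a)) + 2
    n = 2 * half + 1
    return _raster.ellipse_coverage(-half, -half, n, n, 0.0, 0.0, a, b,
                                    0.0, subsample)


def match_filter_bank(patch: np.ndarray, bank: FilterBank | None = None,
                      a_hint: float | None = None,
                      bright_mask: np.ndarray | None = None) -> PupilFit:
    """Pixel-level pupil fit by normalized template matching.

    ``a_hint`` (typically half the tight-rectangle width) restricts the
    bank to the few templates near the expected size.  Bright
    (corneal-reflection) pixels are replaced by the patch median before
    matching.  Raises :class:`NoMatchError` when no template scores at
    least ``bank.score_min`` — such trials are discarded.
    """
    bank = bank or FilterBank()
    patch = np.asarray(patch, dtype=float)
    if bright_mask is not None and bright_mask.any():
        patch = patch.copy()
        patch[bright_mask] = np.median(patch[~bright_mask])
    inv = patch.max() - patch

    radii = list(bank.radii)
    if a_hint is not None:
        near = [r for r in radii if abs(r - a_hint) <= 4.0]
        if not near:
            near = sorted(radii, key=lambda r: abs(r - a_hint))[:2]
        radii = near
    best: PupilFit | None = None
    for a in radii:
        for ar in bank.aspect_ratios:
            b = a * ar
            if b < 2.0:
                continue
            templ = _ellipse_template(a, b)
            if templ.shape[0] > inv.shape[0] or templ.shape[1] > inv.shape[1]:
                continue
            ncc = match_template(inv, templ, pad_input=True)
            iy, ix = np.unravel_index(np.argmax(ncc), ncc.shape)
            score = float(np.clip(ncc[iy, ix], 0.0, 1.0))
            if best is None or score > best.score:
                best = PupilFit(cx=float(ix), cy=float(iy), a=a, b=b,
                                score=score, stage="filter_bank")
    if best is None or best.score < bank.score_min:
        got = 0.0 if best is None else best.score
        raise NoMatchError(f"best template score {got:.2f} below "
                           f"{bank.score_min}")
    return best


# ---------------------------------------------------------------------------
# stage 2: anti-aliased annulus refinement


def refine_annulus(patch: np.ndarray, init: PupilFit,
                   bright_mask: np.ndarray | None = None,
                   band_px: float = 3.0,
                   edge_sigma_px: float = 0.8,
                   xatol: float = 1e-4) -> PupilFit:
    """Subpixel refinement of the pupil ellipse.

    Minimizes the sum of squared residuals between the patch and an
    anti-aliased dark-ellipse-on-light model within an annular band of
    ``band_px`` around the initial ellipse edge, using Nelder-Mead from the
    template-stage initialization (parameter tolerance ``xatol`` px).
    ``edge_sigma_px`` softens the model edge by the optical blur width (see
    a Gaussian edge profile, see below).  The semi-axes are constrained to within one
    pixel of the initialization; if the optimizer pushes against that box
    the result is clipped and flagged low-confidence.
    """
    patch = np.asarray(patch, dtype=float)
    h, w = patch.shape
    ys, xs = np.mgrid[0:h, 0:w]
    px = xs.ravel().astype(float)
    py = ys.ravel().astype(float)
    vals = patch.ravel()
    keep = np.ones(px.size, bool)
    if bright_mask is not None:
        keep &= ~bright_mask.ravel()

    # fixed annular band and intensity levels from the initialization
    c0, s0 = math.cos(init.theta), math.sin(init.theta)
    dx = px - init.cx
    dy = py - init.cy
    u = dx * c0 + dy * s0
    v = -dx * s0 + dy * c0
    rho = np.sqrt((u / init.a) ** 2 + (v / init.b) ** 2)
    scale = math.sqrt(init.a * init.b)
    dist = (rho - 1.0) * scale
    band = keep & (np.abs(dist) <= band_px)
    if band.sum() < 24:
        raise PupilLostError("annulus band has too few usable pixels")
    inner = keep & (rho < 0.6)
    outer = keep & (1.25 < rho) & (rho < 1.9)
    if inner.sum() < 8 or outer.sum() < 8:
        raise PupilLostError("cannot estimate pupil/iris intensity levels")
    i_in = float(np.median(vals[inner]))
    i_out = float(np.median(vals[outer]))

    bpx, bpy, bvals = px[band], py[band], vals[band]
    lo = np.array([init.cx - 2.0, init.cy - 2.0, init.a - 1.0,
                   init.b - 1.0, init.theta - 0.4])
    hi = np.array([init.cx + 2.0, init.cy + 2.0, init.a + 1.0,
                   init.b + 1.0, init.theta + 0.4])

    # The model value of a band pixel is the ellipse indicator convolved
    # with the optical blur and integrated over the pixel square.  Both
    # smoothings are symmetric about the edge, so they compose into a
    # single Gaussian edge profile with variance sigma_edge^2 + 1/12 (the
    # 1/12 being the pixel-aperture variance); one CDF evaluation per
    # pixel then replaces explicit sub-sampling at equal accuracy for the
    # locally straight pupil boundary.
    sigma_eff = math.sqrt(edge_sigma_px ** 2 + 1.0 / 12.0)

    def model_for(p: np.ndarray) -> np.ndarray:
        c, s = math.cos(p[4]), math.sin(p[4])
        dxe = bpx - p[0]
        dye = bpy - p[1]
        ue = dxe * c + dye * s
        ve = -dxe * s + dye * c
        rhoe = np.sqrt((ue / p[2]) ** 2 + (ve / p[3]) ** 2)
        de = (rhoe - 1.0) * math.sqrt(p[2] * p[3])
        cov = ndtr(-de / sigma_eff)
        return i_out + (i_in - i_out) * cov

    def objective(p: np.ndarray) -> float:
        if np.any(p < lo) or np.any(p > hi):
            return 1e18
        r = bvals - model_for(p)
        return float(r @ r)

    x0 = np.array([init.cx, init.cy, init.a, init.b, init.theta])
    res = minimize(objective, x0, method="Nelder-Mead",
                   options={"xatol": xatol, "fatol": 1e-8, "maxfev": 400,
                            "adaptive": True})
    p = res.x
    clipped = bool(np.any(p <= lo) or np.any(p >= hi))
    p = np.clip(p, lo, hi)
    a, b = float(p[2]), float(p[3])
    theta = float(p[4])
    if a < b:  # keep the a >= b convention
        a, b = b, a
        theta += math.pi / 2.0
    model = model_for(np.array([p[0], p[1], a, b, theta]))
    rms = math.sqrt(float(np.mean((bvals - model) ** 2)))
    contrast = abs(i_out - i_in)
    score = float(np.clip(1.0 - rms / contrast, 0.0, 1.0)) if contrast > 0 else 0.0
    return PupilFit(cx=float(p[0]), cy=float(p[1]), a=a, b=b, theta=theta,
                    score=score, stage="annulus", low_confidence=clipped)


# ---------------------------------------------------------------------------
# composition


def pupil_center(frame: Frame, eye_roi: ROIBox,
                 pupil_roi: ROIBox | None = None,
                 bank: FilterBank | None = None,
                 params: DetectionParams | None = None,
                 margin: int = 6) -> PupilFit:
    """Full-frame-coordinate subpixel pupil fit for one frame.

    Crops the eye region, finds (or accepts) the pupil ROI, shrinks it to a
    tight rectangle, runs the template bank and the annulus refinement, and
    maps the center back through the crop offsets.  Propagates every
    discard signal.
    """
    params = params or DetectionParams()
    eye_patch = crop(frame, eye_roi)
    if pupil_roi is None:
        pupil_roi = detect_pupil_region(eye_patch, params)
        if is_absent(pupil_roi) or pupil_roi.confidence < params.confidence_threshold:
            raise LowConfidenceError(
                f"pupil confidence {pupil_roi.confidence:.2f} below "
                f"{params.confidence_threshold}")
    rect = shrink_to_pupil(eye_patch, pupil_roi)
    x0 = max(0, rect.x0 - margin)
    y0 = max(0, rect.y0 - margin)
    w = min(eye_patch.width - x0, rect.w + 2 * margin)
    h = min(eye_patch.height - y0, rect.h + 2 * margin)
    sub = crop(eye_patch, ROIBox(x0, y0, w, h))
    patch = sub.astype_float()
    # corneal reflections: 99th-percentile cut, dilated to also cover the
    # optical-blur skirt around each bright core
    from scipy import ndimage
    bright = ndimage.binary_dilation(
        patch >= np.quantile(eye_patch.astype_float(), 0.99), iterations=2)
    a_hint = rect.w / 2.0
    fit = match_filter_bank(patch, bank, a_hint=a_hint, bright_mask=bright)
    fit = refine_annulus(patch, fit, bright_mask=bright)
    ox, oy = sub.origin
    return replace(fit, cx=fit.cx + ox, cy=fit.cy + oy)


def pupil_diameter_change(fit_a: PupilFit, fit_b: PupilFit) -> float:
    """Signed mean-diameter difference (b minus a) in pixels."""
    return fit_b.mean_diameter - fit_a.mean_diameter
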