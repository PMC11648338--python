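"""Eye / head-marker / pupil region detection with confidence scores.

A deterministic intensity-and-shape detector: dark connected components are
thresholded at a low intensity quantile, filtered by area, and classified by
context — the pupil is a dark ellipse adjacent to bright corneal-reflection
blobs (the eye box is grown around it), while the head marker is a dark,
near-circular blob *outside* the eye box.  That contextual split mirrors the
reason the two regions must be disambiguated at all: in isolation they look
alike.

Each returned box carries a confidence in [0, 1] — the product of a
normalized contrast score and a shape score — and callers discard frames
whose confidence falls below a threshold (blinks, occlusions, missing
features), which keeps the subpixel stages honest.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import measure

from .io import Frame, ROIBox, FormatError

__all__ = [
    "DetectionParams",
    "DetectionResult",
    "detect_regions",
    "detect_pupil_region",
    "load_annotations",
    "save_annotations",
]


@dataclass
class DetectionParams:
    """Knobs for the dark-blob detector.

    ``dark_quantile`` sets the dark threshold as a fractional level within
    the frame's robust intensity range (1st..99th percentile); pixels below
    it are 'dark'.  Area bounds reject specks and frame-scale blobs;
    ``circularity_min`` gates the marker's roundness; boxes with confidence
    below ``confidence_threshold`` are discarded downstream.
    """

    dark_quantile: float = 0.3
    min_area_px: float = 80.0
    max_area_px: float = 20000.0
    circularity_min: float = 0.6
    confidence_threshold: float = 0.5
    min_contrast: float = 10.0       # counts; guards against blank frames
    eye_box_scale: float = 2.6       # eye box half-size, in pupil half-sizes
    margin_px: int = 8               # padding around tight feature bboxes

    def __post_init__(self) -> None:
        if not 0.0 < self.dark_quantile < 1.0:
            raise ValueError("dark_quantile must lie in (0, 1)")
        if not 0 < self.min_area_px < self.max_area_px:
            raise ValueError("area bounds must be positive and ordered")
        for name in ("circularity_min", "confidence_threshold"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


_ABSENT = object()


def _absent_box(label: str) -> ROIBox:
    """1x1 placeholder with confidence 0 meaning 'label not found'."""
    return ROIBox(0, 0, 1, 1, label=label, confidence=0.0)


def is_absent(box: ROIBox) -> bool:
    return box.confidence == 0.0 and box.w == 1 and box.h == 1


@dataclass
class DetectionResult:
    eye: ROIBox
    marker: ROIBox


def _dark_components(img: np.ndarray, params: DetectionParams):
    """Connected dark components with geometry stats, area-filtered."""
    lo, hi = np.quantile(img, [0.001, 0.99])
    if hi - lo < params.min_contrast:
        return []
    thresh = lo + params.dark_quantile * (hi - lo)
    labels = measure.label(img < thresh, connectivity=2)
    comps = []
    for prop in measure.regionprops(labels, intensity_image=img):
        if not params.min_area_px <= prop.area <= params.max_area_px:
            continue
        comps.append(prop)
    return comps


def _contrast_score(img: np.ndarray, prop, params: DetectionParams) -> float:
    """Darkness of the blob relative to its local surround, in [0, 1]."""
    y0, x0, y1, x1 = prop.bbox
    m = params.margin_px + 4
    ry0, rx0 = max(0, y0 - m), max(0, x0 - m)
    ry1, rx1 = min(img.shape[0], y1 + m), min(img.shape[1], x1 + m)
    ring = img[ry0:ry1, rx0:rx1]
    surround = float(np.median(ring))
    inner = float(prop.intensity_mean)
    if surround <= 0:
        return 0.0
    return float(np.clip((surround - inner) / surround, 0.0, 1.0))


def _aspect_score(prop) -> float:
    """Penalize blobs far from the expected near-circular aspect; occlusion
    (blink onset) flattens the pupil blob and drives this toward zero."""
    y0, x0, y1, x1 = prop.bbox
    w, h = x1 - x0, y1 - y0
    aspect = min(w, h) / max(w, h)
    return float(np.clip((aspect - 0.4) / 0.45, 0.0, 1.0))


def _circularity(prop) -> float:
    per = prop.perimeter
    if per <= 0:
        return 0.0
    return float(np.clip(4.0 * np.pi * prop.area / per ** 2, 0.0, 1.0))


def _bright_blobs(img: np.ndarray, full_scale: float) -> np.ndarray:
    """Corneal-reflection candidates: well above the scene's median, toward
    sensor saturation (reflexes of the IR sources are near-saturated)."""
    med = float(np.median(img))
    return img > med + 0.5 * (full_scale - med)


def _clip_box(x0: int, y0: int, w: int, h: int, frame: Frame,
              label: str, confidence: float) -> ROIBox:
    x0 = max(0, x0)
    y0 = max(0, y0)
    w = min(w, frame.width - x0)
    h = min(h, frame.height - y0)
    return ROIBox(x0, y0, w, h, label=label,
                  confidence=float(np.clip(confidence, 0.0, 1.0)))


def detect_regions(frame: Frame,
                   params: DetectionParams | None = None) -> DetectionResult:
    """Locate the eye and head-marker regions in a full frame.

    Returns at most one box per label; a label that cannot be found comes
    back as a 1x1 box with confidence 0 (see :func:`is_absent`), which the
    caller treats as a discard signal.
    """
    params = params or DetectionParams()
    img = frame.astype_float()
    comps = _dark_components(img, params)
    if not comps:
        return DetectionResult(_absent_box("eye"), _absent_box("marker"))

    bright = _bright_blobs(img, float(2 ** frame.bit_depth - 1))
    m = params.margin_px

    # Eye: dark blob with bright reflection pixels in its neighbourhood.
    eye_box = _absent_box("eye")
    pupil_prop = None
    best = 0.0
    for prop in comps:
        y0, x0, y1, x1 = prop.bbox
        g = max(x1 - x0, y1 - y0)
        ny0, nx0 = max(0, y0 - g), max(0, x0 - g)
        ny1, nx1 = min(img.shape[0], y1 + g), min(img.shape[1], x1 + g)
        if not bright[ny0:ny1, nx0:nx1].any():
            continue
        conf = _contrast_score(img, prop, params) * _aspect_score(prop)
        if conf > best:
            best = conf
            pupil_prop = prop
    if pupil_prop is not None:
        y0, x0, y1, x1 = pupil_prop.bbox
        cy, cx = pupil_prop.centroid
        half = params.eye_box_scale * max(x1 - x0, y1 - y0) / 2.0
        eye_box = _clip_box(int(cx - half), int(cy - half),
                            int(2 * half) + 1, int(2 * half) + 1,
                            frame, "eye", best)

    # Marker: near-circular dark blob outside the eye box.
    marker_box = _absent_box("marker")
    best = 0.0
    for prop in comps:
        if prop is pupil_prop:
            continue
        cy, cx = prop.centroid
        if not is_absent(eye_box) and eye_box.contains_point(cx, cy):
            continue
        circ = _circularity(prop)
        if circ < params.circularity_min:
            continue
        conf = _contrast_score(img, prop, params) * circ
        if conf > best:
            best = conf
            y0, x0, y1, x1 = prop.bbox
            marker_box = _clip_box(x0 - m, y0 - m,
                                   (x1 - x0) + 2 * m, (y1 - y0) + 2 * m,
                                   frame, "marker", conf)
    return DetectionResult(eye_box, marker_box)


def detect_pupil_region(eye_patch: Frame,
                        params: DetectionParams | None = None) -> ROIBox:
    """Locate the pupil box inside a cropped eye region (patch coordinates).

    The pupil is the darkest well-formed blob in the patch; occluded or
    absent pupils score low and are discarded by the confidence gate.
    """
    params = params or DetectionParams()
    img = eye_patch.astype_float()
    comps = _dark_components(img, params)
    best_box = _absent_box("pupil")
    best = 0.0
    m = params.margin_px
    for prop in comps:
        conf = _contrast_score(img, prop, params) * _aspect_score(prop)
        if conf > best:
            best = conf
            y0, x0, y1, x1 = prop.bbox
            best_box = _clip_box(x0 - m, y0 - m,
                                 (x1 - x0) + 2 * m, (y1 - y0) + 2 * m,
                                 eye_patch, "pupil", conf)
    return best_box


# ---------------------------------------------------------------------------
# annotation files (external-detector or manual ROIs)

_ANNOT_COLS = ["frame_id", "label", "x0", "y0", "w", "h", "confidence"]


def load_annotations(path: str | Path,
                     frame_sizes: dict[str, tuple[int, int]] | None = None
                     ) -> list[tuple[str, ROIBox]]:
    """Read per-frame ROI annotations from CSV.

    ``frame_sizes`` optionally maps frame_id -> (width, height) for bounds
    validation.  Malformed rows raise a parse error naming the row.
    """
    df = pd.read_csv(path, dtype={"frame_id": str, "label": str})
    missing = set(_ANNOT_COLS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for idx, row in df.iterrows():
        try:
            box = ROIBox(int(row.x0), int(row.y0), int(row.w), int(row.h),
                         label=str(row.label), confidence=float(row.confidence))
            if box.x0 < 0 or box.y0 < 0:
                raise ValueError("negative box origin")
            if frame_sizes is not None and row.frame_id in frame_sizes:
                fw, fh = frame_sizes[row.frame_id]
                if box.x0 + box.w > fw or box.y0 + box.h > fh:
                    raise ValueError(f"box exceeds frame {fw}x{fh}")
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: row {idx}: {exc}") from exc
        out.append((str(row.frame_id), box))
    return out


def save_annotations(boxes: list[tuple[str, ROIBox]],
                     path: str | Path) -> None:
    rows = [{"frame_id": fid, "label": b.label, "x0": b.x0, "y0": b.y0,
             "w": b.w, "h": b.h, "confidence": b.confidence}
            for fid, b in boxes]
    pd.DataFrame(rows, columns=_ANNOT_COLS).to_csv(path, index=False)
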