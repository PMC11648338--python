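"""Core rasters, regions, physical geometry, and file I/O.

Everything downstream (ROI detection, marker/pupil tracking, trial
analysis) works on these containers.  Coordinate convention throughout the
package: 0-based integer pixel indices, a pixel's *center* at integer
coordinates (pixel (i, j) covers the square [i-0.5, i+0.5] x [j-0.5, j+0.5]),
x increasing rightward and y increasing downward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "Frame",
    "ROIBox",
    "GeometryConfig",
    "Displacement2D",
    "FormatError",
    "read_frame",
    "write_frame",
    "crop",
    "degrees_per_pixel",
    "rotation_to_arc_um",
    "read_geometry",
    "write_geometry",
    "read_manifest",
]


class FormatError(ValueError):
    """Raised for unreadable or unsupported image / config files."""


@dataclass
class Frame:
    """A single grayscale raster with its acquisition timestamp.

    Parameters
    ----------
    pixels : ndarray of uint8 or uint16, shape (height, width)
        Non-negative intensities within ``[0, 2**bit_depth - 1]``.
    t_ms : float
        Acquisition time in milliseconds relative to stimulus-motion onset.
        Negative only for pre-onset fixation frames.
    frame_id : str
        Stable identifier used in manifests and result tables.
    origin : (int, int)
        (x0, y0) offset of this raster inside its parent frame; (0, 0) for
        frames read from disk.  Lets subpixel coordinates measured in a crop
        be mapped back to parent-frame coordinates.
    """

    pixels: np.ndarray
    t_ms: float = 0.0
    frame_id: str = ""
    origin: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise FormatError("Frame requires a non-empty 2-D raster")
        if px.dtype not in (np.uint8, np.uint16):
            raise FormatError(f"Frame dtype must be uint8 or uint16, got {px.dtype}")
        self.pixels = px

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def bit_depth(self) -> int:
        return 8 if self.pixels.dtype == np.uint8 else 16

    def astype_float(self) -> np.ndarray:
        return self.pixels.astype(np.float64)


@dataclass
class ROIBox:
    """Axis-aligned region plus detection confidence.

    ``(x0, y0)`` is the top-left pixel; the box spans columns
    ``x0 .. x0+w-1`` and rows ``y0 .. y0+h-1`` of its parent frame.
    """

    x0: int
    y0: int
    w: int
    h: int
    label: str = ""
    confidence: float = 1.0

    VALID_LABELS = ("eye", "marker", "pupil")

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError("ROIBox width/height must be positive")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError("confidence must lie in [0, 1]")
        if self.label and self.label not in self.VALID_LABELS:
            raise ValueError(f"unknown ROI label {self.label!r}")

    def validate_within(self, frame: Frame) -> None:
        if (self.x0 < 0 or self.y0 < 0
                or self.x0 + self.w > frame.width
                or self.y0 + self.h > frame.height):
            raise ValueError(
                f"ROI ({self.x0},{self.y0},{self.w},{self.h}) exceeds "
                f"frame {frame.width}x{frame.height}")

    def contains_point(self, x: float, y: float) -> bool:
        return (self.x0 - 0.5 <= x <= self.x0 + self.w - 0.5
                and self.y0 - 0.5 <= y <= self.y0 + self.h - 0.5)


@dataclass
class GeometryConfig:
    """Physical scale chain: sensor pixels -> object plane -> degrees.

    ``footprint_um_per_px`` is the physical distance on the subject's face
    covered by one image pixel (depends on camera placement, so it is always
    a measured/config input, never derived from lens equations).  The
    degrees-per-pixel factor uses the small-angle arc relation on a sphere
    of the given eye diameter.
    """

    footprint_um_per_px: float
    sensor_pitch_um: float = 3.45
    eye_diameter_mm: float = 22.0
    deg_per_px: float | None = None

    def __post_init__(self) -> None:
        for name in ("footprint_um_per_px", "sensor_pitch_um", "eye_diameter_mm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.deg_per_px is None:
            self.deg_per_px = degrees_per_pixel(self)
        elif not self.deg_per_px > 0:
            raise ValueError("deg_per_px must be strictly positive")

    @classmethod
    def from_deg_per_px(cls, deg_per_px: float,
                        eye_diameter_mm: float = 22.0) -> "GeometryConfig":
        """Geometry whose derived conversion equals ``deg_per_px`` exactly."""
        radius_um = eye_diameter_mm * 1000.0 / 2.0
        footprint = deg_per_px * math.pi / 180.0 * radius_um
        return cls(footprint_um_per_px=footprint, eye_diameter_mm=eye_diameter_mm)

    @property
    def px_per_um(self) -> float:
        return 1.0 / self.footprint_um_per_px


@dataclass
class Displacement2D:
    """Signed subpixel displacement between two frames, in image pixels."""

    dx: float
    dy: float
    frame_pair: tuple[str, str] = ("", "")

    def __post_init__(self) -> None:
        if not (math.isfinite(self.dx) and math.isfinite(self.dy)):
            raise ValueError("displacement components must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.dx, self.dy], dtype=float)

    def __add__(self, other: "Displacement2D") -> "Displacement2D":
        return Displacement2D(self.dx + other.dx, self.dy + other.dy,
                              (self.frame_pair[0], other.frame_pair[1]))

    def __neg__(self) -> "Displacement2D":
        return Displacement2D(-self.dx, -self.dy,
                              (self.frame_pair[1], self.frame_pair[0]))


# ---------------------------------------------------------------------------
# frame I/O


def read_frame(path: str | Path, t_ms: float = 0.0,
               frame_id: str | None = None) -> Frame:
    """Read a single-channel PNG or TIFF raster from disk.

    Intensities are preserved bit-exactly (round trip with
    :func:`write_frame`).  Multi-channel images are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such image file: {path}")
    try:
        px = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - normalize plugin errors
        raise FormatError(f"could not read {path}: {exc}") from exc
    if px.ndim != 2:
        raise FormatError(f"{path}: expected single-channel image, "
                          f"got shape {px.shape}")
    if px.dtype not in (np.uint8, np.uint16):
        raise FormatError(f"{path}: unsupported dtype {px.dtype}")
    return Frame(px, t_ms=t_ms, frame_id=frame_id or path.stem)


def write_frame(frame: Frame, path: str | Path) -> None:
    """Write a frame as grayscale PNG or TIFF, losslessly."""
    path = Path(path)
    if path.suffix.lower() not in (".png", ".tif", ".tiff"):
        raise FormatError(f"unsupported image extension: {path.suffix}")
    iio.imwrite(path, frame.pixels)


def crop(frame: Frame, roi: ROIBox) -> Frame:
    """Extract the ROI as a child frame carrying its parent-frame offset.

    Pixel (0, 0) of the output equals pixel (x0, y0) of the input, and the
    output's ``origin`` accumulates so coordinates always map back to the
    top-level frame: parent = child + origin.
    """
    roi.validate_within(frame)
    sub = frame.pixels[roi.y0:roi.y0 + roi.h, roi.x0:roi.x0 + roi.w]
    ox, oy = frame.origin
    return replace(frame, pixels=sub.copy(),
                   origin=(ox + roi.x0, oy + roi.y0))


# ---------------------------------------------------------------------------
# physical conversions


def degrees_per_pixel(geom: GeometryConfig) -> float:
    """Degrees of ocular rotation per image pixel (small-angle arc)."""
    radius_um = geom.eye_diameter_mm * 1000.0 / 2.0
    return geom.footprint_um_per_px / radius_um * 180.0 / math.pi


def rotation_to_arc_um(angle_deg: float, eye_diameter_mm: float = 22.0) -> float:
    """Arc length (µm) swept on the eyeball surface by a rotation.

    A 0.05 degree rotation of a 22 mm eye moves the pupil by about 10 µm,
    which sets the physical resolution the tracker must reach.
    """
    if not eye_diameter_mm > 0:
        raise ValueError("eye diameter must be positive")
    return eye_diameter_mm * 1000.0 / 2.0 * angle_deg * math.pi / 180.0


# ---------------------------------------------------------------------------
# config / manifest files


_GEOM_KEYS = ("sensor_pitch_um", "footprint_um_per_px",
              "eye_diameter_mm", "deg_per_px")


def read_geometry(path: str | Path) -> GeometryConfig:
    """Read a flat ``key = value`` geometry config file."""
    values: dict[str, float] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected 'key = value'")
        key, _, val = line.partition("=")
        key = key.strip()
        if key not in _GEOM_KEYS:
            raise FormatError(f"{path}:{lineno}: unknown geometry key {key!r}")
        values[key] = float(val)
    if "footprint_um_per_px" not in values:
        raise FormatError(f"{path}: footprint_um_per_px is required")
    return GeometryConfig(**values)


def write_geometry(geom: GeometryConfig, path: str | Path) -> None:
    lines = [f"{k} = {getattr(geom, k)!r}" for k in _GEOM_KEYS]
    Path(path).write_text("\n".join(lines) + "\n")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a trial manifest CSV.

    Required columns: trial_id, frame_id, path, t_ms, stimulus_label.
    Frame paths are resolved relative to the manifest's directory.
    """
    df = pd.read_csv(path, dtype={"trial_id": str, "frame_id": str,
                                  "stimulus_label": str})
    required = {"trial_id", "frame_id", "path", "t_ms", "stimulus_label"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: manifest missing columns {sorted(missing)}")
    base = Path(path).parent
    df["path"] = [str((base / p)) if not Path(p).is_absolute() else p
                  for p in df["path"]]
    return df
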