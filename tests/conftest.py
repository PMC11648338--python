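"""Shared fixtures: synthetic scenes and geometry used across the suite."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from ofrtrack import GeometryConfig, detect_regions
from ofrtrack import synth


@pytest.fixture(scope="session")
def geom40() -> GeometryConfig:
    """Bench geometry: 40 µm object-plane footprint per pixel, 22 mm eye."""
    return GeometryConfig(footprint_um_per_px=40.0)


@pytest.fixture(scope="session")
def geom_clinical() -> GeometryConfig:
    """Clinical geometry: the 0.168 deg/px conversion factor."""
    return GeometryConfig.from_deg_per_px(0.168)


@pytest.fixture(scope="session")
def marker_scene() -> synth.SceneParams:
    """Marker-only bench scene (artificial-calibration style)."""
    return synth.SceneParams(frame_size=(260, 220),
                             marker=synth.MarkerSpec(cx=115.0, cy=105.0),
                             eye=None, seed=7)


@pytest.fixture(scope="session")
def quiet_scene() -> synth.SceneParams:
    """Nominal clinical scene without sensor noise (renderer ground truth)."""
    return synth.SceneParams(
        seed=1, noise=synth.NoiseSpec(gaussian_sd=0.0, poisson_scale=0.0))


@pytest.fixture(scope="session")
def nominal_scene() -> synth.SceneParams:
    """Nominal clinical scene at nominal sensor noise."""
    return synth.SceneParams(seed=1)


def shift_marker(scene: synth.SceneParams, dx: float, dy: float,
                 seed: int) -> synth.SceneParams:
    """Scene with the marker displaced by (dx, dy) px and a fresh noise seed."""
    return dataclasses.replace(
        scene, seed=seed,
        marker=dataclasses.replace(scene.marker, cx=scene.marker.cx + dx,
                                   cy=scene.marker.cy + dy))


def shift_eye(scene: synth.SceneParams, dx: float, dy: float,
              seed: int, **eye_kwargs) -> synth.SceneParams:
    return dataclasses.replace(
        scene, seed=seed,
        eye=dataclasses.replace(scene.eye, cx=scene.eye.cx + dx,
                                cy=scene.eye.cy + dy, **eye_kwargs))


@pytest.fixture(scope="session")
def marker_reference(marker_scene):
    """Rendered reference bench frame with its detected marker ROI."""
    frame = synth.render_scene(marker_scene)
    roi = detect_regions(frame).marker
    return frame, roi
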