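"""Benchmark experiments that qualify the tracker on synthetic ground truth.

Three studies, mirroring how a bench-and-clinic qualification of this kind
of system proceeds:

* **Artificial marker calibration** — a marker on a micromanipulator is
  stepped in fine (7.5 µm) or coarse (22.5 µm) increments up to 180 µm
  along each axis (fine only for the oblique series); the per-axis residual
  SD after a linear regression of estimated (px) on true (µm) displacement
  measures the tracker's bench resolution.
* **Four-frame reliability** — trials with frames at {0, 80, 100, 180} ms:
  the pair sums d01+d13 and d02+d23 both measure the 0 -> 180 ms head
  displacement, so their difference is pure measurement error.
* **End-to-end tracker noise** — full clinical-style trials with programmed
  reflex amplitudes, head drift and pupil-diameter fluctuation; the SD of
  (estimated - programmed) movement-epoch eye-in-head displacement, in
  degrees, is the number that decides whether single-trial reflex
  measurements are usable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detect import detect_regions
from .errors import TrackingError
from .io import GeometryConfig
from .marker import marker_displacement
from .pipeline import (calibration_regression, consistency_error,
                       measure_marker_pairs, process_trial)
from . import synth

__all__ = [
    "CalibrationResult",
    "ConsistencyResult",
    "TrackerNoiseResult",
    "run_marker_calibration",
    "run_consistency_study",
    "run_tracker_noise_study",
]

BENCH_FOOTPRINT_UM = 40.0
CLINICAL_DEG_PER_PX = 0.168


def _bench_scene() -> synth.SceneParams:
    return synth.SceneParams(frame_size=(260, 220),
                             marker=synth.MarkerSpec(cx=115.0, cy=105.0),
                             eye=None)


@dataclass
class CalibrationResult:
    slope_px_per_um: dict[str, float]
    residual_sd_px: dict[str, float]
    n_points: int
    n_discarded: int

    @property
    def worst_residual_sd_px(self) -> float:
        return max(self.residual_sd_px.values())


def run_marker_calibration(seeds: tuple[int, ...] = (1, 2, 3, 4, 5),
                           footprint_um_per_px: float = BENCH_FOOTPRINT_UM,
                           ) -> CalibrationResult:
    """Replicate the micromanipulator sweep and regress estimates on truth.

    Per axis, the horizontal regression pools the horizontal and diagonal
    series and the vertical regression the vertical and diagonal series,
    across all seeds (each seed is an independent noise realization of the
    full sweep).
    """
    geom = GeometryConfig(footprint_um_per_px=footprint_um_per_px)
    scene = _bench_scene()
    truth: dict[str, list[float]] = {"x": [], "y": []}
    est: dict[str, list[float]] = {"x": [], "y": []}
    n_points = n_discarded = 0
    for seed in seeds:
        for series in synth.simulate_calibration(scene, geom, seed=seed):
            ref = series.frames[0]
            roi_ref = detect_regions(ref).marker
            for i, frame in enumerate(series.frames[1:], start=1):
                try:
                    d = marker_displacement(ref, frame, roi_ref,
                                            detect_regions(frame).marker)
                except TrackingError:
                    n_discarded += 1
                    continue
                n_points += 1
                if series.axis in ("h", "diag"):
                    truth["x"].append(series.truth_um[i, 0])
                    est["x"].append(d.dx)
                if series.axis in ("v", "diag"):
                    truth["y"].append(series.truth_um[i, 1])
                    est["y"].append(d.dy)
    slopes, sds = {}, {}
    for axis in ("x", "y"):
        slope, _, sd = calibration_regression(np.array(truth[axis]),
                                              np.array(est[axis]))
        slopes[axis], sds[axis] = slope, sd
    return CalibrationResult(slope_px_per_um=slopes, residual_sd_px=sds,
                             n_points=n_points, n_discarded=n_discarded)


@dataclass
class ConsistencyResult:
    mean_err_px: dict[str, float]
    mean_err_um: dict[str, float]
    n_trials: int
    n_discarded: int

    @property
    def worst_mean_err_um(self) -> float:
        return max(self.mean_err_um.values())


def run_consistency_study(n_trials: int = 100, seed: int = 0,
                          footprint_um_per_px: float = BENCH_FOOTPRINT_UM,
                          head_drift_um_max: float = 40.0,
                          ) -> ConsistencyResult:
    """Four-frame path-consistency errors over simulated reliability trials.

    Each trial renders frames at {0, 80, 100, 180} ms with smooth head
    drift, a programmed reflex, pupil-diameter fluctuation, and nominal
    sensor noise; only the head-marker stream enters the consistency check.
    """
    geom = GeometryConfig(footprint_um_per_px=footprint_um_per_px)
    rng = np.random.default_rng(seed)
    errors = []
    n_discarded = 0
    for k in range(n_trials):
        sim = synth.make_ofr_trial(
            rng, geom, amplitude_deg=float(rng.uniform(0.05, 0.5)),
            stimulus_label="up" if k % 2 else "down",
            schedule_ms=(0.0, 80.0, 100.0, 180.0),
            head_drift_um_max=head_drift_um_max, trial_id=f"rel{k:03d}")
        scene = synth.SceneParams(seed=int(rng.integers(2 ** 31)))
        res = synth.simulate_trial(sim, scene)
        try:
            disps = measure_marker_pairs(res.frames)
            errors.append(consistency_error(disps))
        except TrackingError:
            n_discarded += 1
    err = np.array(errors)
    mean_px = {"x": float(err[:, 0].mean()), "y": float(err[:, 1].mean())}
    mean_um = {ax: v * footprint_um_per_px for ax, v in mean_px.items()}
    return ConsistencyResult(mean_err_px=mean_px, mean_err_um=mean_um,
                             n_trials=len(errors), n_discarded=n_discarded)


@dataclass
class TrackerNoiseResult:
    error_sd_deg: dict[str, float]
    bias_deg: dict[str, float]
    n_valid: int
    n_discarded: int

    @property
    def worst_error_sd_deg(self) -> float:
        return max(self.error_sd_deg.values())


def run_tracker_noise_study(n_trials: int = 200, seed: int = 0,
                            deg_per_px: float = CLINICAL_DEG_PER_PX,
                            head_drift_um_max: float = 40.0,
                            diam_sd_px: float = 0.21,
                            amplitude_range: tuple[float, float] = (0.05, 0.5),
                            ) -> TrackerNoiseResult:
    """End-to-end error of the movement-epoch eye-in-head displacement.

    Runs the full measurement chain (detection, marker tracking, pupil
    fitting, head compensation, degree conversion) on simulated clinical
    trials and compares against the programmed reflex displacement.
    """
    geom = GeometryConfig.from_deg_per_px(deg_per_px)
    rng = np.random.default_rng(seed)
    errors = []
    n_discarded = 0
    for k in range(n_trials):
        label = "up" if k % 2 else "down"
        amp = float(rng.uniform(*amplitude_range))
        sim = synth.make_ofr_trial(rng, geom, amplitude_deg=amp,
                                   stimulus_label=label,
                                   head_drift_um_max=head_drift_um_max,
                                   diam_sd_px=diam_sd_px,
                                   trial_id=f"clin{k:03d}")
        scene = synth.SceneParams(seed=int(rng.integers(2 ** 31)))
        res = synth.simulate_trial(sim, scene)
        rec = process_trial(sim.trial_id, res.frames, label, geom)
        if not rec.valid:
            n_discarded += 1
            continue
        programmed = sim.eye_path_deg[2] - sim.eye_path_deg[1]
        errors.append(rec.movement_disp_deg - programmed)
    err = np.array(errors)
    sd = {"x": float(err[:, 0].std(ddof=1)), "y": float(err[:, 1].std(ddof=1))}
    bias = {"x": float(err[:, 0].mean()), "y": float(err[:, 1].mean())}
    return TrackerNoiseResult(error_sd_deg=sd, bias_deg=bias,
                              n_valid=len(errors), n_discarded=n_discarded)
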