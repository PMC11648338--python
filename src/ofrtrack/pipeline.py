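"""Head-compensated eye displacement, trial validation, and statistics.

The quantity of interest is the eye-in-head displacement over the
open-loop movement window: pupil-center displacement in the image minus
head-marker displacement, converted from pixels to degrees through the
geometry config.  Two epochs matter per trial:

* fixation epoch (0 -> 80 ms): the eye should be still; trials where it is
  not are discarded (their retinal stimulus differed);
* movement epoch (80 -> 160 ms): the reflex displacement that is measured.

The module also provides the two bench analyses used to qualify the
tracker — the linear calibration regression against programmed marker
displacements, and the four-frame path-consistency check (two different
frame-pair sums of the same 0 -> 180 ms displacement must agree; their
difference is pure measurement error) — plus per-subject summary
statistics (Welch two-tailed t tests of up vs down responses).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .detect import DetectionParams, detect_regions, is_absent
from .errors import LowConfidenceError, ScheduleError, TrackingError
from .io import Displacement2D, Frame, GeometryConfig
from .marker import marker_displacement
from .pupil import FilterBank, PupilFit, pupil_center, pupil_diameter_change

__all__ = [
    "TrialRecord",
    "SubjectSummary",
    "eye_in_head_displacement",
    "fixation_gate",
    "ofr_magnitude",
    "consistency_error",
    "measure_marker_pairs",
    "calibration_regression",
    "per_subject_stats",
    "protocol_illumination",
    "process_trial",
]

FIXATION_EPOCH_MS = (0.0, 80.0)
MOVEMENT_EPOCH_MS = (80.0, 160.0)


@dataclass
class TrialRecord:
    """One stimulus presentation and everything measured from it."""

    trial_id: str
    stimulus_label: str
    schedule_ms: tuple[float, ...]
    status: str = "valid"                      # "valid" | "discarded"
    discard_reason: str | None = None
    fixation_disp_px: np.ndarray | None = None
    movement_disp_px: np.ndarray | None = None
    fixation_disp_deg: np.ndarray | None = None
    movement_disp_deg: np.ndarray | None = None
    head_disp_px: dict[tuple[int, int], Displacement2D] = field(
        default_factory=dict)
    pupil_fits: list[PupilFit] = field(default_factory=list)
    pupil_diam_change_px: float | None = None

    @property
    def valid(self) -> bool:
        return self.status == "valid"

    def discard(self, reason: str) -> None:
        self.status = "discarded"
        self.discard_reason = reason
        self.fixation_disp_px = self.movement_disp_px = None
        self.fixation_disp_deg = self.movement_disp_deg = None


@dataclass
class SubjectSummary:
    """Per-subject bookkeeping and the up-vs-down significance tests."""

    subject_id: str
    n_valid: int
    n_discarded: dict[str, int]
    condition_stats: dict[str, dict[str, float]]
    movement_test: tuple[float, float] | None   # (t, p), vertical, up vs down
    fixation_test: tuple[float, float] | None
    tests_omitted: bool = False

    @property
    def n_total(self) -> int:
        return self.n_valid + sum(self.n_discarded.values())


# ---------------------------------------------------------------------------
# per-trial computation


def eye_in_head_displacement(pupil_a: PupilFit, pupil_b: PupilFit,
                             head: Displacement2D) -> Displacement2D:
    """(pupil displacement in the image) minus (head displacement)."""
    return Displacement2D(
        (pupil_b.cx - pupil_a.cx) - head.dx,
        (pupil_b.cy - pupil_a.cy) - head.dy,
        frame_pair=head.frame_pair)


def _frame_at(frames: list[Frame], t_ms: float, tol: float = 1.0) -> Frame:
    for fr in frames:
        if abs(fr.t_ms - t_ms) <= tol:
            return fr
    raise ScheduleError(f"no frame at t = {t_ms:g} ms")


def process_trial(trial_id: str, frames: list[Frame], stimulus_label: str,
                  geom: GeometryConfig,
                  det_params: DetectionParams | None = None,
                  bank: FilterBank | None = None,
                  max_fix_disp_deg: float = 0.2,
                  epochs: tuple[float, float, float] = (0.0, 80.0, 160.0),
                  ) -> TrialRecord:
    """Run the full measurement chain on one trial's frames.

    Any stage can signal a discard (lost marker/pupil, low detection
    confidence, size mismatch, undefined correlation, broken fixation);
    the record then carries the reason instead of displacements.
    """
    det_params = det_params or DetectionParams()
    schedule = tuple(sorted(fr.t_ms for fr in frames))
    rec = TrialRecord(trial_id=trial_id, stimulus_label=stimulus_label,
                      schedule_ms=schedule)
    try:
        f0 = _frame_at(frames, epochs[0])
        f1 = _frame_at(frames, epochs[1])
        f2 = _frame_at(frames, epochs[2])
        dets, fits = {}, {}
        for fr in (f0, f1, f2):
            det = detect_regions(fr, det_params)
            for box in (det.eye, det.marker):
                if is_absent(box) or box.confidence < det_params.confidence_threshold:
                    raise LowConfidenceError(
                        f"{box.label} confidence {box.confidence:.2f} too low "
                        f"in frame {fr.frame_id}")
            dets[fr.frame_id] = det
            fits[fr.frame_id] = pupil_center(fr, det.eye, bank=bank,
                                             params=det_params)
        rec.pupil_fits = [fits[f.frame_id] for f in (f0, f1, f2)]

        head_01 = marker_displacement(f0, f1, dets[f0.frame_id].marker,
                                      dets[f1.frame_id].marker)
        head_12 = marker_displacement(f1, f2, dets[f1.frame_id].marker,
                                      dets[f2.frame_id].marker)
        rec.head_disp_px = {(0, 1): head_01, (1, 2): head_12}

        fix = eye_in_head_displacement(fits[f0.frame_id], fits[f1.frame_id],
                                       head_01)
        mov = eye_in_head_displacement(fits[f1.frame_id], fits[f2.frame_id],
                                       head_12)
        rec.fixation_disp_px = fix.as_array()
        rec.movement_disp_px = mov.as_array()
        rec.fixation_disp_deg = rec.fixation_disp_px * geom.deg_per_px
        rec.movement_disp_deg = rec.movement_disp_px * geom.deg_per_px
        rec.pupil_diam_change_px = pupil_diameter_change(fits[f1.frame_id],
                                                         fits[f2.frame_id])
        fixation_gate(rec, max_fix_disp_deg)
    except TrackingError as exc:
        rec.discard(exc.reason)
    return rec


def fixation_gate(trial: TrialRecord, max_fix_disp_deg: float = 0.2
                  ) -> str:
    """Discard trials in which the eye moved around stimulus onset.

    The gate compares the magnitude of the fixation-epoch eye-in-head
    displacement against ``max_fix_disp_deg``; returns the (possibly
    updated) status.
    """
    if trial.fixation_disp_deg is None:
        return trial.status
    if float(np.hypot(*trial.fixation_disp_deg)) > max_fix_disp_deg:
        trial.discard("fixation_break")
    return trial.status


def ofr_magnitude(trial: TrialRecord, geom: GeometryConfig) -> np.ndarray:
    """Movement-epoch eye-in-head displacement in degrees (x, y)."""
    if not trial.valid or trial.movement_disp_px is None:
        raise ScheduleError("trial has no valid movement-epoch displacement")
    return trial.movement_disp_px * geom.deg_per_px


# ---------------------------------------------------------------------------
# four-frame reliability analysis


def measure_marker_pairs(frames: list[Frame],
                         det_params: DetectionParams | None = None,
                         pairs: tuple[tuple[int, int], ...] = (
                             (0, 1), (1, 3), (0, 2), (2, 3)),
                         ) -> dict[tuple[int, int], Displacement2D]:
    """Head-marker displacements for the requested frame-index pairs."""
    det_params = det_params or DetectionParams()
    dets = []
    for fr in frames:
        det = detect_regions(fr, det_params)
        if is_absent(det.marker) or det.marker.confidence < det_params.confidence_threshold:
            raise LowConfidenceError(f"marker not found in {fr.frame_id}")
        dets.append(det.marker)
    return {(i, j): marker_displacement(frames[i], frames[j],
                                        dets[i], dets[j])
            for i, j in pairs}


def consistency_error(head_disp: dict[tuple[int, int], Displacement2D]
                      ) -> np.ndarray:
    """Four-frame path-consistency error, componentwise absolute, pixels.

    With frames at {t0, t1, t2, t3}, d01 + d13 and d02 + d23 both measure
    the t0 -> t3 displacement; their difference is pure measurement error.
    """
    for pair in ((0, 1), (1, 3), (0, 2), (2, 3)):
        if pair not in head_disp:
            raise ScheduleError(f"missing marker displacement for pair {pair}")
    path_a = head_disp[(0, 1)].as_array() + head_disp[(1, 3)].as_array()
    path_b = head_disp[(0, 2)].as_array() + head_disp[(2, 3)].as_array()
    return np.abs(path_a - path_b)


# ---------------------------------------------------------------------------
# calibration regression


def calibration_regression(true_disp: np.ndarray, est_disp: np.ndarray
                           ) -> tuple[float, float, float]:
    """OLS fit of estimated displacement (px) on true displacement (µm).

    Returns (slope in px/µm, intercept in px, residual SD in px).  The
    residual SD is the figure of merit: how far single estimates scatter
    around the linear response.
    """
    true_disp = np.asarray(true_disp, dtype=float)
    est_disp = np.asarray(est_disp, dtype=float)
    if true_disp.size < 3:
        raise ValueError("need at least 3 calibration points")
    if np.ptp(true_disp) == 0:
        raise ValueError("degenerate calibration: constant truth vector")
    res = stats.linregress(true_disp, est_disp)
    resid = est_disp - (res.slope * true_disp + res.intercept)
    sd = float(np.std(resid, ddof=2)) if resid.size > 2 else 0.0
    return float(res.slope), float(res.intercept), sd


# ---------------------------------------------------------------------------
# per-subject statistics


def _cond_stats(disp: np.ndarray) -> dict[str, float]:
    n = disp.shape[0]
    mean = disp.mean(axis=0)
    sem = (disp.std(axis=0, ddof=1) / math.sqrt(n)) if n > 1 else np.full(2, np.nan)
    return {"n": n, "mean_x": float(mean[0]), "mean_y": float(mean[1]),
            "sem_x": float(sem[0]), "sem_y": float(sem[1])}


def per_subject_stats(trials: list[TrialRecord],
                      subject_id: str = "subject",
                      up_label: str = "up", down_label: str = "down",
                      ) -> SubjectSummary:
    """Summarize one subject's session.

    Vertical movement-epoch displacements for upward- vs downward-drifting
    stimuli are compared with an unpaired two-tailed Welch t test; the same
    test on the fixation epoch should come out non-significant (the eye is
    still before the reflex).  With fewer than 2 valid trials in either
    condition the tests are omitted and flagged.
    """
    n_discarded: dict[str, int] = {}
    by_cond_mov: dict[str, list[np.ndarray]] = {}
    by_cond_fix: dict[str, list[np.ndarray]] = {}
    n_valid = 0
    for tr in trials:
        if not tr.valid:
            reason = tr.discard_reason or "unknown"
            n_discarded[reason] = n_discarded.get(reason, 0) + 1
            continue
        n_valid += 1
        by_cond_mov.setdefault(tr.stimulus_label, []).append(
            tr.movement_disp_deg)
        by_cond_fix.setdefault(tr.stimulus_label, []).append(
            tr.fixation_disp_deg)

    cond_stats = {lab: _cond_stats(np.vstack(v))
                  for lab, v in by_cond_mov.items()}

    movement_test = fixation_test = None
    omitted = True
    up_m = by_cond_mov.get(up_label, [])
    dn_m = by_cond_mov.get(down_label, [])
    if len(up_m) >= 2 and len(dn_m) >= 2:
        omitted = False
        up_y = np.vstack(up_m)[:, 1]
        dn_y = np.vstack(dn_m)[:, 1]
        t, p = stats.ttest_ind(up_y, dn_y, equal_var=False)
        movement_test = (float(t), float(p))
        up_fy = np.vstack(by_cond_fix[up_label])[:, 1]
        dn_fy = np.vstack(by_cond_fix[down_label])[:, 1]
        t, p = stats.ttest_ind(up_fy, dn_fy, equal_var=False)
        fixation_test = (float(t), float(p))
    return SubjectSummary(subject_id=subject_id, n_valid=n_valid,
                          n_discarded=n_discarded, condition_stats=cond_stats,
                          movement_test=movement_test,
                          fixation_test=fixation_test,
                          tests_omitted=omitted)


# ---------------------------------------------------------------------------
# acquisition-protocol arithmetic


def protocol_illumination(n_conditions: int, n_reps: int,
                          frames_per_trial: int, pulse_ms: float,
                          trial_s: float, setup_s: float = 0.0,
                          setup_hz: float = 0.0
                          ) -> tuple[float, float, float]:
    """Session length and total IR-on time for a pulsed-illumination run.

    The illuminators fire only while a frame is exposed (``pulse_ms`` per
    frame), so a 4-condition x 30-rep x 3-frame session of 2 s trials lasts
    4 minutes with just 720 ms of IR illumination; a 30 s focusing period
    at 10 Hz adds another 600 ms.
    Returns (session_min, ir_on_ms, setup_ir_ms).
    """
    for name, v in (("n_conditions", n_conditions), ("n_reps", n_reps),
                    ("frames_per_trial", frames_per_trial),
                    ("pulse_ms", pulse_ms), ("trial_s", trial_s)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    session_min = n_conditions * n_reps * trial_s / 60.0
    ir_on_ms = n_conditions * n_reps * frames_per_trial * pulse_ms
    setup_ir_ms = setup_s * setup_hz * pulse_ms
    return session_min, ir_on_ms, setup_ir_ms
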