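"""Discard signals raised by the tracking stages.

Every error below means "this trial cannot be measured reliably"; the trial
pipeline catches them and books the trial as discarded with the reason,
rather than letting a bad frame contaminate the statistics.
"""


class TrackingError(Exception):
    """Base class for per-trial discard conditions."""

    reason = "tracking_failed"


class MarkerLostError(TrackingError):
    """No dark marker blob found inside the marker ROI."""

    reason = "marker_lost"


class PupilLostError(TrackingError):
    """No dark pupil region found inside the pupil ROI."""

    reason = "pupil_lost"


class SizeMismatchError(TrackingError):
    """Tight marker rectangles differ in size beyond tolerance (large head
    movement or partial occlusion between the two frames)."""

    reason = "size_mismatch"


class UndefinedCorrelationError(TrackingError):
    """A correlation patch has zero intensity variance."""

    reason = "undefined_correlation"


class NoMatchError(TrackingError):
    """No pupil filter-bank template scored above the acceptance threshold."""

    reason = "no_filter_match"


class LowConfidenceError(TrackingError):
    """ROI detection confidence fell below the discard threshold."""

    reason = "low_confidence"


class ScheduleError(TrackingError):
    """Trial lacks the frames required for the requested epoch."""

    reason = "bad_schedule"
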