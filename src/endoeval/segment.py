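"""Attempt segmentation from synchronisation gestures.

Every exercise attempt is delimited by a deliberate raise of the main (right)
hand and arm. On the vertical (Y) position track of the right hand such a
raise appears as a contiguous supra-threshold excursion above the running
baseline. Detection pairs the raises — (1st, 2nd) open/close attempt 1,
(3rd, 4th) attempt 2, and so on — and extracts all stream data strictly
between each pair, excluding the raises themselves. Attempts reaching the
90 s limit were aborted by protocol and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import ABORT_LIMIT_S, MultimodalRecording, Y

__all__ = [
    "GestureParams",
    "GestureEvent",
    "AttemptSegment",
    "SegmentationError",
    "detect_sync_gestures",
    "split_attempts",
    "segment_recording",
]


class SegmentationError(RuntimeError):
    """Raised when a recording cannot be split into attempts."""


@dataclass(frozen=True)
class GestureParams:
    """Detection thresholds for the sync-gesture raise.

    ``height_threshold`` (m) above the running-median baseline, held for at
    least ``min_hold_s``; the baseline window must be long relative to the
    raise so the raise itself does not lift the baseline.

    ``boundary_guard_s`` is trimmed off each segment edge beyond the detected
    raise extent: thresholded detection only sees the raise above the height
    threshold, so without a guard the sub-threshold portions of the raise
    ramps would leak gesture motion into the attempt's kinematics.
    """

    height_threshold: float = 0.25
    min_hold_s: float = 1.0
    baseline_window_s: float = 10.0
    boundary_guard_s: float = 0.25

    def __post_init__(self) -> None:
        if min(self.height_threshold, self.min_hold_s, self.baseline_window_s) <= 0:
            raise ValueError("all gesture parameters must be positive")
        if self.boundary_guard_s < 0:
            raise ValueError("boundary_guard_s must be >= 0")


@dataclass(frozen=True)
class GestureEvent:
    """One detected raise: midpoint timestamp plus on/off extent (s)."""

    t: float
    t_on: float
    t_off: float


@dataclass
class AttemptSegment:
    """All streams of one attempt, sliced on the shared clock."""

    streams: MultimodalRecording
    attempt_index: int
    t_start: float
    t_end: float
    duration_s: float
    aborted: bool


def detect_sync_gestures(
    y: np.ndarray,
    t: np.ndarray,
    params: GestureParams | None = None,
    *,
    name: str = "recording",
) -> list[GestureEvent]:
    """Detect hand-raise gestures on a vertical position series.

    A gesture is a contiguous excursion of ``y`` at least ``height_threshold``
    above its centred running median, lasting at least ``min_hold_s``. Returns
    one event per excursion, ordered by (strictly increasing) midpoint.
    Raises :class:`SegmentationError` when fewer than two are found.
    """
    params = params or GestureParams()
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    if y.size != t.size or y.size < 3:
        raise ValueError("y and t must be equal-length series with >= 3 samples")
    rate = (t.size - 1) / (t[-1] - t[0])
    win = max(3, int(round(params.baseline_window_s * rate)) | 1)
    baseline = (
        pd.Series(y).rolling(win, center=True, min_periods=1).median().to_numpy()
    )
    above = (y - baseline) >= params.height_threshold

    events: list[GestureEvent] = []
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[~above[edges]] + 1) if edges.size else []
    if above[0]:
        starts = [0] + starts
    ends = list(edges[above[edges]] + 1) if edges.size else []
    if above[-1]:
        ends = ends + [y.size]
    for s, e in zip(starts, ends):
        t_on, t_off = t[s], t[e - 1]
        if t_off - t_on >= params.min_hold_s:
            events.append(GestureEvent((t_on + t_off) / 2.0, float(t_on), float(t_off)))
    if len(events) < 2:
        raise SegmentationError(
            f"{name}: found {len(events)} sync gesture(s); at least 2 are required"
        )
    return events


def _slice_stream(values: np.ndarray, t: np.ndarray, t0: float, t1: float):
    m = (t > t0) & (t < t1)
    return values[..., m], t[m]


def split_attempts(
    recording: MultimodalRecording,
    gestures: list[GestureEvent] | list[float],
    *,
    abort_limit_s: float = ABORT_LIMIT_S,
    first_attempt_index: int = 1,
    guard_s: float = 0.0,
) -> list[AttemptSegment]:
    """Pair gestures (1,2), (3,4), ... and slice each attempt's streams.

    With :class:`GestureEvent` inputs the slice runs from the end of the
    opening raise to the start of the closing raise (the raises themselves
    are excluded); with bare timestamps it runs between the marks. An odd
    gesture count leaves an unpaired gesture and is an error.
    """
    if len(gestures) % 2:
        raise SegmentationError(
            f"{recording.meta}: odd gesture count {len(gestures)} (unpaired gesture)"
        )
    segments: list[AttemptSegment] = []
    for i in range(0, len(gestures), 2):
        g0, g1 = gestures[i], gestures[i + 1]
        if isinstance(g0, GestureEvent):
            t0, t1 = g0.t_off + guard_s, g1.t_on - guard_s
        else:
            t0, t1 = float(g0), float(g1)
        if t1 <= t0:
            raise SegmentationError(f"{recording.meta}: non-increasing gesture pair at {t0}")
        semg, semg_t = _slice_stream(recording.semg, recording.semg_t, t0, t1)
        ori, ori_t = _slice_stream(recording.orientation, recording.orientation_t, t0, t1)
        skel, skel_t = _slice_stream(recording.skeleton, recording.skeleton_t, t0, t1)
        sliced = MultimodalRecording(
            semg=semg,
            semg_t=semg_t,
            orientation=ori,
            orientation_t=ori_t,
            skeleton=skel,
            skeleton_t=skel_t,
            meta=recording.meta,
        )
        duration = t1 - t0
        segments.append(
            AttemptSegment(
                streams=sliced,
                attempt_index=first_attempt_index + i // 2,
                t_start=t0,
                t_end=t1,
                duration_s=min(duration, abort_limit_s),
                aborted=duration >= abort_limit_s - 0.5,
            )
        )
    return segments


def segment_recording(
    recording: MultimodalRecording,
    params: GestureParams | None = None,
    boundaries: list[tuple[float, float]] | None = None,
) -> list[AttemptSegment]:
    """Segment one continuous recording into its attempts.

    Detects the right-hand raises automatically unless an explicit
    ``boundaries`` override (list of ``(t_start, t_end)`` pairs, mirroring
    the study's manual marking protocol) is supplied.
    """
    apf = len(recording.attempt_truth) or None
    first = 1
    if recording.meta.file_index and apf:
        first = (recording.meta.file_index - 1) * apf + 1
    elif recording.meta.file_index:
        first = (recording.meta.file_index - 1) * 3 + 1
    if boundaries is not None:
        flat = [t for pair in boundaries for t in pair]
        return split_attempts(recording, flat, first_attempt_index=first)
    hand_y = recording.skeleton[recording.part_index("Hand_R"), Y]
    events = detect_sync_gestures(
        hand_y, recording.skeleton_t, params, name=str(recording.meta)
    )
    guard = (params or GestureParams()).boundary_guard_s
    return split_attempts(recording, events, first_attempt_index=first, guard_s=guard)
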