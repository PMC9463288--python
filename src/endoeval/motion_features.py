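"""Motion analysis parameters (MAPs) of one attempt, per tracked body part.

Seven MAPs per part: path length (Trace), average speed (Velocity), vertical
direction reversals (POC, "point of view changes between up and down"), and
summary statistics of the angle between the body axis and the part's limb
segment (Angle_Mean/Max/Min/Range).

Interpretation choices, since the source protocol leaves them open:

* the "normal vector of the body part" is the limb-segment vector from the
  part's parent joint (hand -> wrist, wrist -> elbow, elbow -> shoulder
  centre, head -> shoulder centre, shoulder centre -> head);
* the body axis is the trunk direction (shoulder centre -> head) per frame,
  falling back to the global vertical when it degenerates;
* POC counts vertical movement reversals debounced with a 2 cm hysteresis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth import BODY_PARTS, Y

__all__ = [
    "BodyPartTrack",
    "MotionFeatures",
    "MAP_NAMES",
    "PARENT_OF",
    "DEFAULT_POC_HYSTERESIS_M",
    "trace_and_velocity",
    "poc",
    "segment_angles",
    "body_axis",
    "part_features",
]

MAP_NAMES = (
    "POC",
    "Trace",
    "Velocity",
    "Angle_Mean",
    "Angle_Max",
    "Angle_Min",
    "Angle_Range",
)

#: Parent joint used for each part's limb-segment vector.
PARENT_OF = {
    "Head": "Spine_Shoulders",
    "Spine_Shoulders": "Head",
    "Elbow_L": "Spine_Shoulders",
    "Wrist_L": "Elbow_L",
    "Hand_L": "Wrist_L",
    "Elbow_R": "Spine_Shoulders",
    "Wrist_R": "Elbow_R",
    "Hand_R": "Wrist_R",
}

DEFAULT_POC_HYSTERESIS_M = 0.02


@dataclass(frozen=True)
class BodyPartTrack:
    """Positions (T x 3, metres) of one body part with timestamps (s)."""

    part: str
    positions: np.ndarray
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.positions, dtype=float)
        t = np.asarray(self.timestamps, dtype=float)
        if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] != t.size or t.size < 2:
            raise ValueError("positions must be T x 3 with matching timestamps, T >= 2")
        if not np.all(np.isfinite(p)):
            raise ValueError(f"{self.part}: non-finite coordinates")
        object.__setattr__(self, "positions", p)
        object.__setattr__(self, "timestamps", t)


@dataclass(frozen=True)
class MotionFeatures:
    POC: float
    Trace: float
    Velocity: float
    Angle_Mean: float
    Angle_Max: float
    Angle_Min: float
    Angle_Range: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in MAP_NAMES}


def trace_and_velocity(track: BodyPartTrack) -> tuple[float, float]:
    """Path length (m) and average speed (m/s) of a track."""
    dt = track.timestamps[-1] - track.timestamps[0]
    if dt <= 0:
        raise ValueError(f"{track.part}: zero track duration")
    steps = np.linalg.norm(np.diff(track.positions, axis=0), axis=1)
    trace = float(steps.sum())
    return trace, trace / float(dt)


def poc(track: BodyPartTrack, hysteresis: float = DEFAULT_POC_HYSTERESIS_M) -> int:
    """Vertical (Y) movement-direction reversals, debounced by ``hysteresis``.

    A reversal is counted only once the part has moved at least ``hysteresis``
    metres in the new vertical direction since the last extremum; the initial
    direction is established, not counted.
    """
    y = track.positions[:, Y]
    if y.size < 3:
        raise ValueError(f"{track.part}: need >= 3 samples for POC")
    direction = 0  # +1 rising, -1 falling, 0 undetermined
    hi = lo = y[0]  # running extrema while direction undetermined
    extremum = y[0]
    count = 0
    for v in y[1:]:
        if direction == 0:
            hi = max(hi, v)
            lo = min(lo, v)
            if hi - v >= hysteresis:
                direction = -1  # establishing move, not counted
                extremum = v
            elif v - lo >= hysteresis:
                direction = 1
                extremum = v
        elif direction == 1:
            if v > extremum:
                extremum = v
            elif extremum - v >= hysteresis:
                direction = -1
                extremum = v
                count += 1
        else:
            if v < extremum:
                extremum = v
            elif v - extremum >= hysteresis:
                direction = 1
                extremum = v
                count += 1
    return count


def body_axis(
    head: np.ndarray, shoulder_centre: np.ndarray, eps: float = 1e-9
) -> np.ndarray:
    """Per-frame trunk axis (T x 3): shoulder centre -> head, unit length.

    Frames where the trunk vector degenerates fall back to global vertical.
    """
    axis = np.asarray(head, dtype=float) - np.asarray(shoulder_centre, dtype=float)
    norm = np.linalg.norm(axis, axis=1, keepdims=True)
    vertical = np.zeros_like(axis)
    vertical[:, Y] = 1.0
    ok = norm[:, 0] > eps
    out = np.where(ok[:, None], axis / np.where(ok[:, None], norm, 1.0), vertical)
    return out


def segment_angles(
    track: BodyPartTrack,
    parent: BodyPartTrack,
    axis: np.ndarray,
    eps: float = 1e-9,
) -> tuple[float, float, float, float]:
    """(Angle_Mean, Angle_Max, Angle_Min, Angle_Range) in degrees.

    Per frame: the angle in [0, 180] between the limb-segment vector
    (part position - parent position) and the body-axis vector. Frames with a
    degenerate segment vector are skipped; if every frame degenerates, all
    four statistics are NaN (missing feature).
    """
    if track.positions.shape != parent.positions.shape:
        raise ValueError("track and parent must be time-aligned")
    axis = np.asarray(axis, dtype=float)
    seg = track.positions - parent.positions
    seg_norm = np.linalg.norm(seg, axis=1)
    ax_norm = np.linalg.norm(axis, axis=1)
    ok = (seg_norm > eps) & (ax_norm > eps)
    if not np.any(ok):
        nan = float("nan")
        return nan, nan, nan, nan
    cosang = np.einsum("ij,ij->i", seg[ok], axis[ok]) / (seg_norm[ok] * ax_norm[ok])
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    a_max = float(ang.max())
    a_min = float(ang.min())
    return float(ang.mean()), a_max, a_min, a_max - a_min


def part_features(
    tracks: dict[str, BodyPartTrack],
    part: str,
    hysteresis: float = DEFAULT_POC_HYSTERESIS_M,
) -> MotionFeatures:
    """All seven MAPs of one body part, given the full set of 8 tracks."""
    track = tracks[part]
    trace, velocity = trace_and_velocity(track)
    n_poc = poc(track, hysteresis)
    axis = body_axis(
        tracks["Head"].positions, tracks["Spine_Shoulders"].positions
    )
    a_mean, a_max, a_min, a_range = segment_angles(track, tracks[PARENT_OF[part]], axis)
    return MotionFeatures(
        POC=float(n_poc),
        Trace=trace,
        Velocity=velocity,
        Angle_Mean=a_mean,
        Angle_Max=a_max,
        Angle_Min=a_min,
        Angle_Range=a_range,
    )


def tracks_from_recording(rec) -> dict[str, BodyPartTrack]:
    """Build the 8 body-part tracks from a (sliced) recording."""
    return {
        part: BodyPartTrack(part, rec.part_track(part), rec.skeleton_t)
        for part in BODY_PARTS
    }
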