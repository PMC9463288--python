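"""Per-attempt feature vectors assembled into exercise-level tables.

Each attempt is represented by 160 canonical metrics: the 13 sEMG features
computed once per armband channel (104 columns, named ``feature@chN``) and
the 7 motion analysis parameters computed once per body part (56 columns,
named ``feature@Part``). The four orientation metrics (Roll/Pitch/Yaw AUC
and FES) cannot be fitted inside a 160-column layout under any per-channel /
per-part multiplication, so they are computed and carried as optional extra
columns outside the canonical 160 and outside any count that cites 160.

Tables are pandas DataFrames with annotation columns (participant,
endoscope, exercise, attempt) followed by metric columns.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .emg_features import (
    DEFAULT_BAND,
    EMG_FEATURE_NAMES,
    IMU_FEATURE_NAMES,
    FeatureError,
    channel_features,
    imu_features,
)
from .motion_features import (
    DEFAULT_POC_HYSTERESIS_M,
    MAP_NAMES,
    part_features,
    tracks_from_recording,
)
from .segment import AttemptSegment, GestureParams, segment_recording
from .synth import BODY_PARTS, MultimodalRecording

__all__ = [
    "ANNOTATION_COLS",
    "N_CHANNELS",
    "canonical_columns",
    "imu_columns",
    "assemble",
    "build_feature_tables",
    "impute_group_means",
    "normalize_minmax",
]

ANNOTATION_COLS = ("participant", "endoscope", "exercise", "attempt", "aborted")
N_CHANNELS = 8


def canonical_columns() -> list[str]:
    """The 160 canonical metric names: 13 sEMG x 8 channels + 7 MAPs x 8 parts."""
    emg = [f"{feat}@ch{c + 1}" for feat in EMG_FEATURE_NAMES for c in range(N_CHANNELS)]
    maps = [f"{feat}@{part}" for part in BODY_PARTS for feat in MAP_NAMES]
    return emg + maps


def imu_columns() -> list[str]:
    """The 4 optional orientation metric names (outside the canonical 160)."""
    return list(IMU_FEATURE_NAMES)


def assemble(
    segment: AttemptSegment,
    band: tuple[float, float] = DEFAULT_BAND,
    per_sample: bool = True,
    signed_f_range: bool = True,
    poc_hysteresis: float = DEFAULT_POC_HYSTERESIS_M,
    include_imu: bool = True,
) -> dict[str, float]:
    """Compute one attempt's full feature vector (160 canonical + 4 optional).

    Degenerate streams (for example a too-short channel) yield NaN entries
    and a warning instead of aborting the attempt.
    """
    rec = segment.streams
    out: dict[str, float] = {}
    f_maxes: list[float] = []
    for c in range(N_CHANNELS):
        t = rec.semg_t
        rate = (t.size - 1) / (t[-1] - t[0]) if t.size > 1 else float("nan")
        try:
            feats = channel_features(
                rec.semg[c], rate, band, per_sample=per_sample, signed_f_range=signed_f_range
            ).as_dict()
            f_maxes.append(feats["f_Max"])
        except (FeatureError, ValueError) as err:
            warnings.warn(f"{rec.meta} ch{c + 1}: {err}; features set to NaN", stacklevel=2)
            feats = {name: float("nan") for name in EMG_FEATURE_NAMES}
        for name, value in feats.items():
            out[f"{name}@ch{c + 1}"] = value

    tracks = tracks_from_recording(rec)
    for part in BODY_PARTS:
        try:
            feats = part_features(tracks, part, hysteresis=poc_hysteresis).as_dict()
        except ValueError as err:
            warnings.warn(f"{rec.meta} {part}: {err}; MAPs set to NaN", stacklevel=2)
            feats = {name: float("nan") for name in MAP_NAMES}
        for name, value in feats.items():
            out[f"{name}@{part}"] = value

    if include_imu:
        try:
            f_max_mean = float(np.nanmean(f_maxes)) if f_maxes else float("nan")
            imu = imu_features(
                rec.orientation[0],
                rec.orientation[1],
                rec.orientation[2],
                f_max_mean,
                per_sample=per_sample,
            ).as_dict()
        except (FeatureError, ValueError) as err:
            warnings.warn(f"{rec.meta} IMU: {err}; features set to NaN", stacklevel=2)
            imu = {name: float("nan") for name in IMU_FEATURE_NAMES}
        out.update(imu)
    return out


def build_feature_tables(
    recordings: list[MultimodalRecording],
    gesture_params: GestureParams | None = None,
    **assemble_kwargs,
) -> dict[int, pd.DataFrame]:
    """Segment every recording and assemble one feature table per exercise.

    Rows are attempts, annotated with participant, endoscope, exercise and
    attempt index (1-9); columns follow :func:`canonical_columns` plus the
    optional orientation metrics.
    """
    rows: list[dict] = []
    for rec in recordings:
        for seg in segment_recording(rec, gesture_params):
            row = {
                "participant": rec.meta.participant,
                "endoscope": rec.meta.endoscope,
                "exercise": rec.meta.exercise,
                "attempt": seg.attempt_index,
                "aborted": seg.aborted,
            }
            row.update(assemble(seg, **assemble_kwargs))
            rows.append(row)
    df = pd.DataFrame(rows)
    metric_cols = [c for c in df.columns if c not in ANNOTATION_COLS]
    ordered = list(ANNOTATION_COLS) + metric_cols
    tables = {}
    for ex, sub in df.groupby("exercise"):
        tables[int(ex)] = (
            sub[ordered].sort_values(["participant", "attempt"]).reset_index(drop=True)
        )
    return tables


def _metric_cols(tbl: pd.DataFrame) -> list[str]:
    return [c for c in tbl.columns if c not in ANNOTATION_COLS]


def impute_group_means(tbl: pd.DataFrame) -> pd.DataFrame:
    """Fill missing metric values with the exercise x endoscope group mean.

    Preserves group means, so downstream group contrasts are unbiased by
    missingness; columns missing for a whole group fall back to the overall
    column mean.
    """
    out = tbl.copy()
    cols = _metric_cols(out)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN group slices
        out[cols] = out.groupby("endoscope")[cols].transform(lambda s: s.fillna(s.mean()))
        out[cols] = out[cols].fillna(out[cols].mean())
    return out


def normalize_minmax(tbl: pd.DataFrame) -> pd.DataFrame:
    """Min-max normalise every metric column over all attempts of the table.

    Each column is mapped to [0, 1] by ``(x - min) / (max - min)`` across all
    participants of the exercise; constant columns map to 0.5. Idempotent up
    to the constant-column rule.
    """
    if len(tbl) < 2:
        raise ValueError("need at least 2 rows to normalize")
    out = tbl.copy()
    cols = _metric_cols(out)
    x = out[cols].to_numpy(dtype=float)
    lo = np.nanmin(x, axis=0)
    hi = np.nanmax(x, axis=0)
    span = hi - lo
    const = ~(span > 0)
    span_safe = np.where(const, 1.0, span)
    z = (x - lo) / span_safe
    z[:, const] = 0.5
    out[cols] = z
    return out
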