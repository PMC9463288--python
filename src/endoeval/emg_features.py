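"""Armband-side features of one attempt: 13 per-channel sEMG metrics + 4 IMU metrics.

The 13 sEMG features per channel split into spectral (f_Max, f_Min, f_Range,
P_Max, P_Min, from a band-limited mean-removed periodogram), amplitude
(V_Max, V_Min, V_Range, V_RMS, V_Var) and morphology (V_SSC sign-slope
changes, V_ZC zero crossings, V_WFL waveform length) groups. The orientation
stream contributes Roll/Pitch/Yaw area-under-curve and the FES ratio of the
dominant sEMG frequency to the mean orientation AUC.

Extensive metrics — those growing with attempt length (V_SSC, V_ZC, V_WFL
and the orientation AUCs) — are averaged by the attempt's sample count by
default, so attempts of different duration stay comparable; the averaged set
is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "Spectrum",
    "EmgChannelFeatures",
    "ImuFeatures",
    "FeatureError",
    "DEFAULT_BAND",
    "EMG_FEATURE_NAMES",
    "IMU_FEATURE_NAMES",
    "power_spectrum",
    "spectral_features",
    "amplitude_features",
    "morphology_features",
    "imu_features",
    "channel_features",
]

#: Analysis band (Hz): above DC/motion drift, below the armband Nyquist edge.
DEFAULT_BAND = (10.0, 95.0)

EMG_FEATURE_NAMES = (
    "f_Max",
    "f_Min",
    "f_Range",
    "P_Max",
    "P_Min",
    "V_Max",
    "V_Min",
    "V_Range",
    "V_RMS",
    "V_SSC",
    "V_ZC",
    "V_WFL",
    "V_Var",
)

IMU_FEATURE_NAMES = ("Roll_AUC", "Pitch_AUC", "Yaw_AUC", "FES")


class FeatureError(ValueError):
    """Raised when a stream is too degenerate for feature extraction."""


@dataclass(frozen=True)
class Spectrum:
    """One-sided power spectral density restricted to an analysis band."""

    frequencies: np.ndarray
    power: np.ndarray
    band: tuple[float, float]


@dataclass(frozen=True)
class EmgChannelFeatures:
    f_Max: float
    f_Min: float
    f_Range: float
    P_Max: float
    P_Min: float
    V_Max: float
    V_Min: float
    V_Range: float
    V_RMS: float
    V_SSC: float
    V_ZC: float
    V_WFL: float
    V_Var: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in EMG_FEATURE_NAMES}


@dataclass(frozen=True)
class ImuFeatures:
    Roll_AUC: float
    Pitch_AUC: float
    Yaw_AUC: float
    FES: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in IMU_FEATURE_NAMES}


def power_spectrum(
    x: np.ndarray, rate: float, band: tuple[float, float] = DEFAULT_BAND
) -> Spectrum:
    """Mean-removed periodogram of ``x`` restricted to ``band`` (Hz).

    Uses a plain (boxcar) one-sided periodogram in density scaling, so the
    full-band integral recovers the signal variance (Parseval).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 64:
        raise FeatureError(f"signal too short for a spectrum ({x.size} < 64 samples)")
    lo, hi = band
    if not 0 <= lo < hi <= rate / 2:
        raise ValueError(f"band {band} outside (0, rate/2]")
    f, p = sps.periodogram(x, fs=rate, detrend="constant")
    m = (f >= lo) & (f <= hi)
    return Spectrum(frequencies=f[m], power=p[m], band=(lo, hi))


def spectral_features(s: Spectrum) -> tuple[float, float, float, float, float]:
    """(f_Max, f_Min, f_Range, P_Max, P_Min) of a spectrum.

    f_Max/f_Min are the most/least powerful frequencies; ties break toward
    the lowest frequency. f_Range = f_Max - f_Min is kept signed (negative
    when the least powerful frequency lies above the most powerful).
    """
    if s.power.size == 0:
        raise FeatureError("empty spectrum")
    i_max = int(np.argmax(s.power))
    i_min = int(np.argmin(s.power))
    f_max = float(s.frequencies[i_max])
    f_min = float(s.frequencies[i_min])
    return f_max, f_min, f_max - f_min, float(s.power[i_max]), float(s.power[i_min])


def amplitude_features(x: np.ndarray) -> tuple[float, float, float, float, float]:
    """(V_Max, V_Min, V_Range, V_RMS, V_Var); variance uses the N divisor."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise FeatureError("empty signal")
    v_max = float(x.max())
    v_min = float(x.min())
    return (
        v_max,
        v_min,
        v_max - v_min,
        float(np.sqrt(np.mean(x**2))),
        float(np.var(x)),
    )


def morphology_features(
    x: np.ndarray, per_sample: bool = True
) -> tuple[float, float, float]:
    """(V_SSC, V_ZC, V_WFL) of a signal.

    Sign-slope changes count samples where consecutive first differences have
    strictly opposite sign; zero crossings count strictly sign-changing sample
    pairs (samples exactly at zero do not count); waveform length is the sum
    of absolute sample-to-sample changes. With ``per_sample`` each is divided
    by the sample count.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise FeatureError(f"need >= 3 samples for morphology features ({x.size})")
    d = np.diff(x)
    ssc = float(np.count_nonzero(d[:-1] * d[1:] < 0))
    zc = float(np.count_nonzero(x[:-1] * x[1:] < 0))
    wfl = float(np.abs(d).sum())
    if per_sample:
        n = x.size
        return ssc / n, zc / n, wfl / n
    return ssc, zc, wfl


def imu_features(
    roll: np.ndarray,
    pitch: np.ndarray,
    yaw: np.ndarray,
    f_max_mean: float,
    per_sample: bool = True,
) -> ImuFeatures:
    """Orientation AUCs and the frequency/AUC ratio (FES).

    AUC is the trapezoidal integral of the absolute trace over sample index
    (divided by the sample count when ``per_sample``); FES divides the mean
    dominant sEMG frequency (averaged over the 8 channels) by the mean of the
    three AUCs, and is NaN when that mean is zero.
    """
    traces = [np.asarray(a, dtype=float) for a in (roll, pitch, yaw)]
    n = traces[0].size
    if any(a.size != n for a in traces) or n < 2:
        raise FeatureError("roll/pitch/yaw must be equal-length with >= 2 samples")
    if f_max_mean < 0:
        raise ValueError("f_max_mean must be >= 0")
    aucs = [float(np.trapezoid(np.abs(a))) for a in traces]
    if per_sample:
        aucs = [a / n for a in aucs]
    mean_auc = float(np.mean(aucs))
    fes = f_max_mean / mean_auc if mean_auc > 0 else float("nan")
    return ImuFeatures(aucs[0], aucs[1], aucs[2], fes)


def channel_features(
    x: np.ndarray,
    rate: float,
    band: tuple[float, float] = DEFAULT_BAND,
    per_sample: bool = True,
    signed_f_range: bool = True,
) -> EmgChannelFeatures:
    """All 13 features of one sEMG channel."""
    f_max, f_min, f_range, p_max, p_min = spectral_features(power_spectrum(x, rate, band))
    if not signed_f_range:
        f_range = abs(f_range)
    v_max, v_min, v_range, v_rms, v_var = amplitude_features(x)
    ssc, zc, wfl = morphology_features(x, per_sample=per_sample)
    return EmgChannelFeatures(
        f_Max=f_max,
        f_Min=f_min,
        f_Range=f_range,
        P_Max=p_max,
        P_Min=p_min,
        V_Max=v_max,
        V_Min=v_min,
        V_Range=v_range,
        V_RMS=v_rms,
        V_SSC=ssc,
        V_ZC=zc,
        V_WFL=wfl,
        V_Var=v_var,
    )
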