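"""Seeded synthetic cohort generator for multimodal endoscopic-training recordings.

Real study recordings (8-channel forearm sEMG, armband orientation, Kinect-style
skeleton tracking) are not publicly available, so this module emulates them with
the statistical structure the downstream analysis assumes:

* a 2D-endoscope vs 3D-endoscope group split with a configurable multiplicative
  effect on sEMG amplitude for the 2D group,
* a configurable per-attempt fractional decrease of right hand/wrist speed
  (a learning trend on motion velocity),
* synchronisation gestures (right hand/arm raises) delimiting every attempt,
* the 90 s abort rule for over-long attempts.

Each participant performs 3 exercises x 9 attempts; recordings are captured
continuously in files of 3 attempts, mirroring the study protocol.

The sEMG model is band-limited coloured noise (energy concentrated in 20-95 Hz)
modulated by burst envelopes during simulated tool actions, with sparse
motor-unit-like transients that dominate the signal extrema, in Myo-like
arbitrary amplitude units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

ENDOSCOPE_MODES = ("2D", "3D")

#: Tracked body parts, in canonical order (Kinect-style upper-body subset).
BODY_PARTS = (
    "Head",
    "Spine_Shoulders",
    "Elbow_L",
    "Wrist_L",
    "Hand_L",
    "Elbow_R",
    "Wrist_R",
    "Hand_R",
)

#: Index of the vertical coordinate in skeleton position triples (x, y, z).
Y = 1

# Resting-pose anchors (metres, camera frame: x lateral, y up, z depth).
_ANCHORS = {
    "Head": (0.00, 1.70, 2.00),
    "Spine_Shoulders": (0.00, 1.45, 2.00),
    "Elbow_L": (-0.25, 1.15, 1.90),
    "Wrist_L": (-0.30, 1.05, 1.75),
    "Hand_L": (-0.32, 1.00, 1.65),
    "Elbow_R": (0.25, 1.15, 1.90),
    "Wrist_R": (0.30, 1.05, 1.75),
    "Hand_R": (0.32, 1.00, 1.65),
}

# Working speeds during an attempt (m/s); right-side parts additionally carry
# the learning trend.
_PART_SPEED = {
    "Head": 0.010,
    "Spine_Shoulders": 0.008,
    "Elbow_L": 0.060,
    "Wrist_L": 0.100,
    "Hand_L": 0.120,
    "Elbow_R": 0.060,
    "Wrist_R": 0.100,
    "Hand_R": 0.120,
}
_TRENDED_PARTS = frozenset({"Hand_R", "Wrist_R"})

# sEMG amplitude model (arbitrary Myo-like units). The coloured-noise floor is
# kept small relative to the transient amplitude so the signal is spiky: the
# extrema features (V_Max/V_Min/V_Range) then sit on a much larger scale than
# the variance, as surface EMG recorded through an 8-bit armband does.
_EMG_ACTIVE_SD = 5.0
_EMG_QUIET_FRACTION = 0.12
_EMG_BAND = (20.0, 95.0)
_SPIKE_RATE_HZ = 0.25  # transients per second per channel during an attempt
_SPIKE_AMP = (60.0, 85.0)
_CHANNEL_GAINS = np.array([1.00, 0.92, 1.08, 0.85, 1.15, 0.95, 1.05, 0.90])

# Timeline layout of one continuous 3-attempt file (seconds).
GESTURE_DURATION_S = 1.5
GESTURE_RAISE_M = 0.40
_LEAD_IN_S = 3.0
_GAP_S = 4.0
_TAIL_S = 3.0

ABORT_LIMIT_S = 90.0


class ConfigError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of a synthetic training cohort.

    Defaults mirror the emulated study: 15 volunteers split 7 (2D endoscope)
    vs 8 (3D), three exercises of nine attempts recorded continuously in
    three-attempt files, with three participants later excluded for data
    corruption. ``effect_amplitude`` multiplies 2D-group sEMG amplitudes;
    ``effect_trend`` is the fractional per-attempt decrease of right
    hand/wrist speed.
    """

    n_participants: int = 15
    n_excluded: int = 3
    exercises: int = 3
    attempts_per_exercise: int = 9
    attempts_per_file: int = 3
    group_split: tuple[int, int] = (7, 8)
    emg_rate: float = 200.0
    imu_rate: float = 50.0
    skeleton_rate: float = 30.0
    #: log-normal attempt durations: mode (s) and log-scale sigma, capped at 90 s.
    duration_mode_s: float = 45.0
    duration_sigma: float = 0.35
    effect_amplitude: float = 1.5
    effect_trend: float = 0.05
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.emg_rate, self.imu_rate, self.skeleton_rate) <= 0:
            raise ConfigError("all sampling rates must be positive")
        if sum(self.group_split) != self.n_participants:
            raise ConfigError(
                f"group_split {self.group_split} does not sum to "
                f"n_participants={self.n_participants}"
            )
        if not 0 < self.duration_mode_s <= ABORT_LIMIT_S:
            raise ConfigError("duration mode must lie in (0, 90] s")
        if self.effect_amplitude < 1.0:
            raise ConfigError("effect_amplitude must be >= 1")
        if not 0.0 <= self.effect_trend < 1.0:
            raise ConfigError("effect_trend must lie in [0, 1)")
        if self.attempts_per_exercise % self.attempts_per_file:
            raise ConfigError("attempts_per_exercise must be a multiple of attempts_per_file")

    @property
    def files_per_exercise(self) -> int:
        return self.attempts_per_exercise // self.attempts_per_file

    @property
    def participant_ids(self) -> tuple[str, ...]:
        return tuple(f"P{i + 1:02d}" for i in range(self.n_participants))

    def endoscope_of(self, participant: str) -> str:
        idx = self.participant_ids.index(participant)
        return "2D" if idx < self.group_split[0] else "3D"


@dataclass(frozen=True)
class RecordingMeta:
    participant: str
    endoscope: str
    exercise: int
    file_index: int


@dataclass
class MultimodalRecording:
    """One continuous multi-attempt capture of all three sensor streams.

    ``semg`` is 8 x T1 (arbitrary units), ``orientation`` 3 x T2
    (roll/pitch/yaw, radians), ``skeleton`` 8 parts x 3 coords x T3 (metres);
    each stream carries its own strictly increasing timestamp vector (s).
    ``attempt_truth`` records the generator's ground-truth attempt intervals
    ``(t_start, t_end, aborted)`` for validating downstream segmentation.
    """

    semg: np.ndarray
    semg_t: np.ndarray
    orientation: np.ndarray
    orientation_t: np.ndarray
    skeleton: np.ndarray
    skeleton_t: np.ndarray
    meta: RecordingMeta
    attempt_truth: list[tuple[float, float, bool]] = field(default_factory=list)

    def part_index(self, part: str) -> int:
        return BODY_PARTS.index(part)

    def part_track(self, part: str) -> np.ndarray:
        """T3 x 3 position track of one body part."""
        return self.skeleton[self.part_index(part)].T


def _smooth_noise(rng: Generator, n: int, window: int) -> np.ndarray:
    """Unit-variance Gaussian noise smoothed with a moving average."""
    x = rng.standard_normal(n)
    x = uniform_filter1d(x, size=max(window, 1), mode="nearest")
    sd = x.std()
    return x / sd if sd > 0 else x


def _coloured_emg_noise(rng: Generator, n: int, rate: float) -> np.ndarray:
    """Band-limited (20-95 Hz) unit-variance noise — the sEMG carrier."""
    lo, hi = _EMG_BAND
    nyq = rate / 2.0
    sos = sps.butter(4, (lo / nyq, min(hi / nyq, 0.99)), btype="bandpass", output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n + 400))[200:-200]
    return x / x.std()


def _draw_durations(rng: Generator, cfg: CohortConfig, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Truncated log-normal attempt durations with abort flags at the 90 s cap."""
    mu = np.log(cfg.duration_mode_s) + cfg.duration_sigma**2
    d = rng.lognormal(mu, cfg.duration_sigma, size=n)
    aborted = d >= ABORT_LIMIT_S
    return np.minimum(d, ABORT_LIMIT_S), aborted


def _file_timeline(durations: np.ndarray) -> tuple[float, list[dict]]:
    """Lay out gestures/attempts on the file clock; returns total length and events."""
    t = _LEAD_IN_S
    events = []
    for d in durations:
        g_open = (t, t + GESTURE_DURATION_S)
        t = g_open[1]
        attempt = (t, t + float(d))
        t = attempt[1]
        g_close = (t, t + GESTURE_DURATION_S)
        t = g_close[1] + _GAP_S
        events.append({"open": g_open, "attempt": attempt, "close": g_close})
    return t - _GAP_S + _TAIL_S, events


def _interval_mask(t: np.ndarray, intervals: list[tuple[float, float]]) -> np.ndarray:
    m = np.zeros(t.size, dtype=bool)
    for a, b in intervals:
        m |= (t >= a) & (t < b)
    return m


def _simulate_file(
    rng: Generator,
    cfg: CohortConfig,
    meta: RecordingMeta,
    participant_gain: float,
    first_attempt: int,
) -> MultimodalRecording:
    n_att = cfg.attempts_per_file
    durations, aborted = _draw_durations(rng, cfg, n_att)
    total_s, events = _file_timeline(durations)

    attempt_iv = [e["attempt"] for e in events]
    gesture_iv = [iv for e in events for iv in (e["open"], e["close"])]

    amp_factor = cfg.effect_amplitude if meta.endoscope == "2D" else 1.0

    # --- sEMG -------------------------------------------------------------
    n1 = int(round(total_s * cfg.emg_rate))
    t1 = np.arange(n1) / cfg.emg_rate
    att_mask = _interval_mask(t1, attempt_iv)
    # burst envelope: quiet floor outside attempts, modulated activity inside
    burst = 0.55 + 0.45 * np.abs(_smooth_noise(rng, n1, int(0.4 * cfg.emg_rate)))
    envelope = np.where(att_mask, burst, _EMG_QUIET_FRACTION)
    semg = np.empty((8, n1))
    for c in range(8):
        carrier = _coloured_emg_noise(rng, n1, cfg.emg_rate)
        x = _EMG_ACTIVE_SD * _CHANNEL_GAINS[c] * participant_gain * envelope * carrier
        # sparse biphasic transients during attempts set the signal extrema
        for a, b in attempt_iv:
            n_spikes = rng.poisson(_SPIKE_RATE_HZ * (b - a))
            if n_spikes == 0:
                n_spikes = 1  # every attempt produces at least one burst peak
            locs = rng.uniform(a, b, size=n_spikes)
            amps = rng.uniform(*_SPIKE_AMP, size=n_spikes) * rng.choice((-1.0, 1.0), n_spikes)
            for loc, amp in zip(locs, amps):
                k = int(loc * cfg.emg_rate)
                if 1 <= k < n1 - 1:
                    x[k - 1] += 0.4 * amp * _CHANNEL_GAINS[c] * participant_gain
                    x[k] += amp * _CHANNEL_GAINS[c] * participant_gain
                    x[k + 1] -= 0.5 * amp * _CHANNEL_GAINS[c] * participant_gain
        x *= amp_factor
        x += 0.3 * cfg.noise_sd * rng.standard_normal(n1)  # sensor noise floor
        semg[c] = x

    # --- orientation (roll/pitch/yaw, rad) --------------------------------
    n2 = int(round(total_s * cfg.imu_rate))
    t2 = np.arange(n2) / cfg.imu_rate
    att2 = _interval_mask(t2, attempt_iv)
    orientation = np.empty((3, n2))
    for axis in range(3):
        wander = 0.30 * _smooth_noise(rng, n2, int(2.0 * cfg.imu_rate))
        orientation[axis] = (
            np.where(att2, wander, 0.25 * wander)
            + 0.01 * cfg.noise_sd * rng.standard_normal(n2)
        )

    # --- skeleton ----------------------------------------------------------
    n3 = int(round(total_s * cfg.skeleton_rate))
    t3 = np.arange(n3) / cfg.skeleton_rate
    att3 = _interval_mask(t3, attempt_iv)
    # per-attempt speed factors: learning trend on right hand/wrist + 5% noise
    att_index = np.full(n3, -1)
    for i, (a, b) in enumerate(attempt_iv):
        att_index[(t3 >= a) & (t3 < b)] = i
    trend_factors = (1.0 - cfg.effect_trend) ** (first_attempt - 1 + np.arange(n_att))
    speed_noise = rng.lognormal(0.0, 0.02, size=n_att)

    skeleton = np.empty((8, 3, n3))
    step_norm = 1.5958  # E||N(0, I3)|| — converts per-axis step sd to mean speed
    theta = 0.02  # weak pull toward the resting anchor keeps tracks bounded
    for p, part in enumerate(BODY_PARTS):
        v_active = _PART_SPEED[part]
        v = np.where(att3, v_active, 0.2 * v_active)
        if part in _TRENDED_PARTS:
            f = np.ones(n3)
            for i in range(n_att):
                f[att_index == i] = trend_factors[i] * speed_noise[i]
            v = v * f
        sigma = v / (cfg.skeleton_rate * step_norm)
        steps = np.stack(
            [_smooth_noise(rng, n3, int(0.3 * cfg.skeleton_rate)) for _ in range(3)], axis=1
        )
        inc = sigma[:, None] * steps
        # pin each attempt's realised mean speed to its target exactly, so the
        # injected learning trend is the dominant between-attempt structure
        norms = np.linalg.norm(inc, axis=1)
        for i, (a, b) in enumerate(attempt_iv):
            m = att_index == i
            realised = norms[m].mean() * cfg.skeleton_rate
            target = v[m].mean()
            if realised > 0:
                inc[m] *= target / realised
        anchor = np.asarray(_ANCHORS[part])
        # AR(1) deviation from anchor: d_k = (1-theta) d_{k-1} + sigma_k * step_k
        dev = sps.lfilter([1.0], [1.0, -(1.0 - theta)], inc, axis=0)
        pos = anchor + dev
        pos += 0.0005 * cfg.noise_sd * rng.standard_normal((n3, 3))
        skeleton[p] = pos.T

    # sync-gesture raises on the right arm (hand, wrist, lightly the elbow)
    raise_profile = np.zeros(n3)
    for a, b in gesture_iv:
        ramp = 0.15
        up = np.clip((t3 - a) / ramp, 0.0, 1.0) * np.clip((b - t3) / ramp, 0.0, 1.0)
        raise_profile += GESTURE_RAISE_M * np.clip(up, 0.0, 1.0)
    for part, scale in (("Hand_R", 1.0), ("Wrist_R", 0.9), ("Elbow_R", 0.4)):
        skeleton[BODY_PARTS.index(part), Y] += scale * raise_profile

    truth = [
        (float(iv[0]), float(iv[1]), bool(ab)) for iv, ab in zip(attempt_iv, aborted)
    ]
    return MultimodalRecording(
        semg=semg,
        semg_t=t1,
        orientation=orientation,
        orientation_t=t2,
        skeleton=skeleton,
        skeleton_t=t3,
        meta=meta,
        attempt_truth=truth,
    )


def simulate_cohort(config: CohortConfig | None = None, **overrides) -> list[MultimodalRecording]:
    """Simulate every recording file of a training cohort.

    Returns ``n_participants * exercises * files_per_exercise`` recordings,
    bit-reproducible under a fixed ``config.seed``. Keyword overrides build a
    modified copy of ``config`` (or of the defaults).
    """
    cfg = replace(config or CohortConfig(), **overrides) if overrides else (config or CohortConfig())
    root = SeedSequence(cfg.seed)
    recordings: list[MultimodalRecording] = []
    participant_seeds = root.spawn(cfg.n_participants)
    for pi, (pid, pseed) in enumerate(zip(cfg.participant_ids, participant_seeds)):
        endoscope = cfg.endoscope_of(pid)
        prng = default_rng(pseed)
        participant_gain = float(prng.lognormal(0.0, 0.05))
        file_seeds = pseed.spawn(cfg.exercises * cfg.files_per_exercise)
        k = 0
        for ex in range(1, cfg.exercises + 1):
            for fi in range(1, cfg.files_per_exercise + 1):
                meta = RecordingMeta(pid, endoscope, ex, fi)
                first_attempt = (fi - 1) * cfg.attempts_per_file + 1
                rng = default_rng(file_seeds[k])
                k += 1
                recordings.append(
                    _simulate_file(rng, cfg, meta, participant_gain, first_attempt)
                )
    return recordings


def exclude_participants(
    cohort: list[MultimodalRecording], ids: list[str] | tuple[str, ...]
) -> tuple[list[MultimodalRecording], int]:
    """Drop every recording of the listed participants.

    Returns the reduced cohort and the number of removed attempt-datasets
    (one dataset = one attempt of one exercise).
    """
    present = {r.meta.participant for r in cohort}
    unknown = set(ids) - present
    if unknown:
        raise KeyError(f"unknown participant ids: {sorted(unknown)}")
    drop = set(ids)
    kept, removed_attempts = [], 0
    for r in cohort:
        if r.meta.participant in drop:
            removed_attempts += len(r.attempt_truth)
        else:
            kept.append(r)
    return kept, removed_attempts


def default_excluded_ids(cfg: CohortConfig) -> tuple[str, ...]:
    """The cohort's documented exclusion: the last ``n_excluded`` participants.

    Taking them from the tail of the roster removes one 2D and two 3D
    volunteers under the default 7/8 split — exclusion ids are otherwise
    arbitrary (the study excluded three volunteers for data corruption).
    """
    if cfg.n_excluded == 0:
        return ()
    ids = cfg.participant_ids
    # one from the 2D block, the rest from the 3D tail, to keep groups usable
    n2d = cfg.group_split[0]
    picks = [ids[n2d - 1]] + list(ids[-(cfg.n_excluded - 1):]) if cfg.n_excluded > 1 else [ids[-1]]
    return tuple(picks[: cfg.n_excluded])
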