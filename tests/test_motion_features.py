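import numpy as np
import pytest

from endoeval.motion_features import (
    BodyPartTrack,
    body_axis,
    part_features,
    poc,
    segment_angles,
    trace_and_velocity,
    tracks_from_recording,
)
from .oracles import angle_oracle, poc_oracle, trace_oracle


def _track(positions, duration=None, part="Hand_R"):
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    t = np.linspace(0.0, duration if duration else n / 30.0, n)
    return BodyPartTrack(part, positions, t)


class TestTraceVelocity:
    def test_straight_line_any_sampling(self, rng):
        # points sampled irregularly along the segment (0,0,0)->(3,4,0)
        frac = np.sort(np.concatenate([[0.0, 1.0], rng.uniform(0, 1, 20)]))
        pos = np.outer(frac, [3.0, 4.0, 0.0])
        trace, vel = trace_and_velocity(_track(pos, duration=2.0))
        assert trace == pytest.approx(5.0)
        assert vel == pytest.approx(2.5)

    def test_stationary_track(self):
        trace, vel = trace_and_velocity(_track(np.ones((10, 3))))
        assert trace == 0.0 and vel == 0.0

    def test_unit_square_path(self):
        square = [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0), (0, 0, 0)]
        trace, vel = trace_and_velocity(_track(square, duration=4.0))
        assert trace == pytest.approx(trace_oracle(square)) == pytest.approx(4.0)
        assert vel == pytest.approx(1.0)

    def test_rigid_motion_invariance(self, rng):
        pos = rng.standard_normal((50, 3))
        base, _ = trace_and_velocity(_track(pos))
        # random rotation (QR of a random matrix) + translation
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        moved, _ = trace_and_velocity(_track(pos @ q.T + [5.0, -2.0, 1.0]))
        assert moved == pytest.approx(base, rel=1e-9)

    def test_zero_duration_is_error(self):
        with pytest.raises(ValueError):
            trace_and_velocity(BodyPartTrack("Hand_R", np.zeros((3, 3)), np.zeros(3)))


class TestPoc:
    def test_monotone_ascent_has_no_reversals(self):
        pos = np.zeros((50, 3))
        pos[:, 1] = np.linspace(0, 1, 50)
        assert poc(_track(pos)) == 0

    def test_three_sine_periods_six_reversals(self):
        t = np.linspace(0, 3 * 2 * np.pi, 1000)
        pos = np.zeros((t.size, 3))
        pos[:, 1] = 0.5 * np.sin(t)  # amplitude >> hysteresis
        assert poc(_track(pos), hysteresis=0.02) == 6

    def test_sub_hysteresis_jitter_suppressed(self, rng):
        pos = np.zeros((200, 3))
        pos[:, 1] = 0.002 * rng.standard_normal(200)  # swings stay under 2 cm
        assert poc(_track(pos), hysteresis=0.02) == 0

    def test_matches_swing_extraction_oracle(self, rng):
        for _ in range(50):
            y = np.cumsum(rng.standard_normal(rng.integers(10, 200))) * 0.01
            pos = np.zeros((y.size, 3))
            pos[:, 1] = y
            assert poc(_track(pos), 0.02) == poc_oracle(list(y), 0.02)


class TestSegmentAngles:
    def test_parallel_segment_zero_angle(self):
        n = 20
        axis = np.tile([0.0, 1.0, 0.0], (n, 1))
        child = _track(np.tile([0.0, 2.0, 0.0], (n, 1)))
        parent = _track(np.tile([0.0, 1.0, 0.0], (n, 1)), part="Wrist_R")
        mean, amax, amin, arange = segment_angles(child, parent, axis)
        assert (mean, amax, amin, arange) == (0.0, 0.0, 0.0, 0.0)

    def test_orthogonal_segment_90_degrees(self):
        n = 20
        axis = np.tile([0.0, 1.0, 0.0], (n, 1))
        child = _track(np.tile([1.0, 0.0, 0.0], (n, 1)))
        parent = _track(np.zeros((n, 3)), part="Wrist_R")
        mean, *_ = segment_angles(child, parent, axis)
        assert mean == pytest.approx(90.0)

    def test_diagonal_is_45_degrees(self):
        n = 5
        axis = np.tile([0.0, 1.0, 0.0], (n, 1))
        child = _track(np.tile([1.0, 1.0, 0.0], (n, 1)))
        parent = _track(np.zeros((n, 3)), part="Wrist_R")
        mean, *_ = segment_angles(child, parent, axis)
        assert mean == pytest.approx(45.0)

    def test_scale_invariance(self, rng):
        n = 30
        child_pos = rng.standard_normal((n, 3)) + 2
        parent_pos = rng.standard_normal((n, 3))
        axis = rng.standard_normal((n, 3))
        a = segment_angles(_track(child_pos), _track(parent_pos, part="Wrist_R"), axis)
        b = segment_angles(
            _track(7.5 * child_pos), _track(7.5 * parent_pos, part="Wrist_R"), 7.5 * axis
        )
        assert a == pytest.approx(b, rel=1e-9)

    def test_matches_per_frame_oracle(self, rng):
        n = 40
        child_pos = rng.standard_normal((n, 3))
        parent_pos = rng.standard_normal((n, 3))
        axis = rng.standard_normal((n, 3))
        mean, amax, amin, arange = segment_angles(
            _track(child_pos), _track(parent_pos, part="Wrist_R"), axis
        )
        ref = angle_oracle(child_pos.tolist(), parent_pos.tolist(), axis.tolist())
        assert mean == pytest.approx(np.mean(ref), rel=1e-10)
        assert amax == pytest.approx(max(ref), rel=1e-10)
        assert amin == pytest.approx(min(ref), rel=1e-10)

    def test_all_degenerate_frames_missing(self):
        n = 10
        same = np.ones((n, 3))
        out = segment_angles(_track(same), _track(same, part="Wrist_R"),
                             np.tile([0.0, 1.0, 0.0], (n, 1)))
        assert all(np.isnan(v) for v in out)


def test_body_axis_falls_back_to_vertical():
    head = np.ones((5, 3))
    axis = body_axis(head, head)  # degenerate trunk
    assert np.allclose(axis, np.tile([0.0, 1.0, 0.0], (5, 1)))


def test_right_hand_velocity_declines_with_trend():
    """Injected per-attempt speed trend shows up in attempt-mean velocity."""
    from endoeval.segment import segment_recording
    from endoeval.synth import CohortConfig, simulate_cohort

    means = np.zeros(9)
    n_reps = 20
    for seed in range(n_reps):
        cfg = CohortConfig(seed=300 + seed, n_participants=2, n_excluded=0,
                           group_split=(1, 1), exercises=1, effect_trend=0.05)
        for rec in simulate_cohort(cfg):
            for seg in segment_recording(rec):
                tracks = tracks_from_recording(seg.streams)
                _, vel = trace_and_velocity(tracks["Hand_R"])
                means[seg.attempt_index - 1] += vel
    means /= n_reps * 2
    assert np.all(np.diff(means) < 0)
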