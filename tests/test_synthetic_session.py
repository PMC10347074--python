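"""The session simulator: schedule bookkeeping, determinism, signal physics."""

import numpy as np
import pytest

from armuse.annotation import frames_to_epochs
from armuse.errors import ConfigurationError
from armuse.signal_io import LABEL_FUNCTIONAL, LABEL_NON_FUNCTIONAL, LABEL_UNKNOWN, AnnotationTrack
from armuse.synthetic_session import (
    SessionConfig,
    simulate_session,
    standard_schedule,
    truth_functional_minutes,
)


def test_gravity_only_session_has_unit_norm(quiet_session):
    for sig in (quiet_session.left, quiet_session.right):
        assert np.allclose(sig.norm, 1.0, atol=1e-12)


def test_same_seed_gives_bit_identical_sessions(standard_session):
    again = simulate_session(standard_session.config)
    for a, b in ((standard_session.left, again.left), (standard_session.right, again.right)):
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y) and np.array_equal(a.z, b.z)
    assert np.array_equal(standard_session.left_truth.labels, again.left_truth.labels)


def test_different_seeds_differ():
    cfg = SessionConfig([("walking", 30.0)], seed=0)
    other = SessionConfig([("walking", 30.0)], seed=1)
    assert not np.array_equal(simulate_session(cfg).left.x, simulate_session(other).left.x)


def test_schedule_bookkeeping_functional_fraction():
    """60 s walking + 60 s functional -> functional fraction of labeled
    (non-calibration) frames is 0.5 within one frame per block boundary."""
    cfg = SessionConfig(
        [("calibration", 6.0), ("walking", 60.0), ("functional_bout", 60.0), ("calibration", 6.0)],
        seed=3,
    )
    labels = simulate_session(cfg).left_truth.labels
    labeled = labels[labels != LABEL_UNKNOWN]
    frac = np.mean(labeled == LABEL_FUNCTIONAL)
    assert frac == pytest.approx(0.5, abs=2 / labeled.size)


def test_sample_and_frame_counts_match_durations():
    cfg = SessionConfig([("quiet_sitting", 33.4), ("walking", 21.1)], seed=0)
    sess = simulate_session(cfg)
    assert abs(sess.left.n_samples - cfg.duration_s * 30.0) <= 1
    assert abs(sess.left_truth.n_frames - cfg.duration_s * 25.0) <= 1
    assert sess.left_truth.duration_s == pytest.approx(sess.left.duration_s, abs=1 / 25)


def test_calibration_blocks_are_unknown_category():
    cfg = SessionConfig(
        [("calibration", 6.0), ("quiet_sitting", 30.0), ("calibration", 6.0)], seed=5
    )
    labels = simulate_session(cfg).left_truth.labels
    # frames in [0, 6) s and the last 6 s are category 0
    assert (labels[: int(6 * 25) - 1] == LABEL_UNKNOWN).all()
    assert (labels[-(int(6 * 25) - 1):] == LABEL_UNKNOWN).all()
    mid = labels[int(8 * 25): int(30 * 25)]
    assert (mid == LABEL_NON_FUNCTIONAL).all()


def test_right_sensor_is_delayed_by_clock_offset():
    base = dict(activity_schedule=[("functional_bout", 30.0)], noise_sd_g=0.0, seed=9)
    lagged = simulate_session(SessionConfig(clock_offset_s=0.5, **base))
    aligned = simulate_session(SessionConfig(clock_offset_s=0.0, **base))
    k = 15  # 0.5 s at 30 Hz
    assert np.allclose(lagged.right.x[k:], aligned.right.x[:-k], atol=1e-9)
    # the truth track is in scene time: identical regardless of sensor lag
    assert np.array_equal(lagged.right_truth.labels, aligned.right_truth.labels)


def test_walking_has_dominant_swing_near_1hz():
    cfg = SessionConfig([("walking", 60.0)], noise_sd_g=0.0, seed=21)
    sig = simulate_session(cfg).left
    # anatomical z carries the swing; native frame is a signed permutation
    from armuse.signal_io import to_anatomical

    z = to_anatomical(sig).z
    freqs = np.fft.rfftfreq(z.size, 1 / 30.0)
    peak = freqs[np.argmax(np.abs(np.fft.rfft(z - z.mean())))]
    assert 0.8 <= peak <= 1.2


def test_functional_bout_has_higher_norm_variance_than_walking():
    cfg = SessionConfig(
        [("walking", 60.0), ("functional_bout", 60.0)], noise_sd_g=0.0, seed=13
    )
    sig = simulate_session(cfg).left
    n = sig.n_samples // 2
    assert sig.norm[n:].var() > sig.norm[:n].var()


def test_truth_functional_minutes_formula():
    """n functional epochs x 4 s / 60; e.g. 231 -> 15.4 min, 185 -> 12.33 min."""
    for n_func, expected in ((231, 15.4), (185, 12.33), (0, 0.0)):
        labels = np.concatenate(
            [
                np.full(n_func * 100, LABEL_FUNCTIONAL, dtype=np.int8),
                np.full(50 * 100, LABEL_NON_FUNCTIONAL, dtype=np.int8),
            ]
        )
        track = AnnotationTrack(frame_rate_fps=25.0, labels=labels)
        series = frames_to_epochs(track)
        assert series.functional_minutes() == pytest.approx(expected, abs=0.005)


def test_truth_functional_minutes_on_session():
    cfg = SessionConfig([("functional_bout", 80.0), ("quiet_sitting", 40.0)], seed=2)
    sess = simulate_session(cfg)
    minutes = truth_functional_minutes(sess, "left")
    assert minutes == pytest.approx(80.0 / 60.0, abs=2 * 4 / 60)


@pytest.mark.parametrize(
    "schedule",
    [
        [],
        [("quiet_sitting", -5.0)],
        [("jumping", 10.0)],
    ],
)
def test_invalid_schedules_rejected(schedule):
    with pytest.raises(ConfigurationError):
        SessionConfig(schedule)


def test_negative_noise_rejected():
    with pytest.raises(ConfigurationError):
        SessionConfig([("walking", 10.0)], noise_sd_g=-0.1)


def test_standard_schedule_is_calibration_bounded():
    sched = standard_schedule(np.random.default_rng(0))
    assert sched[0][0] == "calibration" and sched[-1][0] == "calibration"
    assert sum(d for _, d in sched) == SessionConfig(sched).duration_s
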