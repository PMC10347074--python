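"""Calibration detection, lag estimation, and trimming."""

import numpy as np
import pytest

from armuse.errors import SyncError
from armuse.signal_io import to_anatomical
from armuse.synchronizer import (
    SyncResult,
    detect_calibration,
    estimate_lag,
    shift_to_scene_time,
    sync_session,
    trim_to_calibration,
)
from armuse.synthetic_session import SessionConfig, simulate_session

from conftest import make_signal


def _anatomical(session, side="left"):
    return to_anatomical(getattr(session, side))


def test_detects_both_calibration_events(standard_session):
    spans = detect_calibration(_anatomical(standard_session))
    assert len(spans) == 2
    # events injected at [0, 6) s and the final 6 s of the 222 s session
    assert spans[0][0] == pytest.approx(3.0, abs=3.0)
    assert spans[0][1] <= 6.5
    assert spans[1][0] >= 215.5
    assert spans[1][1] == pytest.approx(222.0, abs=3.0)


def test_quiet_session_has_no_calibration(quiet_session):
    with pytest.raises(SyncError):
        detect_calibration(_anatomical(quiet_session))


def test_threshold_above_burst_amplitude_fails(standard_session):
    with pytest.raises(SyncError):
        detect_calibration(_anatomical(standard_session), threshold_g=50.0)


def test_subgravity_threshold_rejected(standard_session):
    with pytest.raises(SyncError):
        detect_calibration(_anatomical(standard_session), threshold_g=0.5)


def test_lag_of_identical_signals_is_zero(standard_session):
    left = _anatomical(standard_session)
    assert estimate_lag(left, left) == 0.0


def test_recovers_constructed_half_second_shift(standard_session):
    left = _anatomical(standard_session)
    right = _anatomical(standard_session, "right")  # generated with 0.5 s lag
    lag = estimate_lag(left, right, window=(0.0, 8.0))
    assert lag == pytest.approx(0.5, abs=1 / 30.0)


def test_flat_signal_lag_undefined():
    flat = make_signal(np.ones((3, 300)))
    with pytest.raises(SyncError, match="flat"):
        estimate_lag(flat, flat)


def test_shift_beyond_search_range_flagged():
    cfg = SessionConfig(
        [("calibration", 6.0), ("quiet_sitting", 30.0), ("calibration", 6.0)],
        clock_offset_s=3.0,
        seed=4,
    )
    sess = simulate_session(cfg)
    with pytest.raises(SyncError, match="boundary"):
        estimate_lag(
            to_anatomical(sess.left), to_anatomical(sess.right),
            max_lag_s=2.0, window=(0.0, 8.0),
        )


def test_lag_recovery_over_seeded_sessions():
    """Median absolute recovery error over sessions with lags in ±2 s stays
    below one sample period."""
    errors = []
    for i in range(6):
        rng = np.random.default_rng(200 + i)
        offset = float(rng.uniform(-2.0, 2.0))
        cfg = SessionConfig(
            [("calibration", 6.0), ("walking", 30.0), ("calibration", 6.0)],
            clock_offset_s=offset,
            seed=300 + i,
        )
        sess = simulate_session(cfg)
        sync = sync_session(to_anatomical(sess.left), to_anatomical(sess.right))
        errors.append(abs(sync.lag_right_vs_left_s - offset))
    assert np.median(errors) <= 1 / 30.0


def test_trim_interval_arithmetic(standard_session):
    left = _anatomical(standard_session)
    sync = SyncResult(
        first_calibration_end_s=6.0,
        second_calibration_start_s=216.0,
        lag_right_vs_left_s=0.5,
        spot_check_drift_s=0.0,
    )
    sig, track = trim_to_calibration(left, standard_session.left_truth, sync)
    assert sig.duration_s == pytest.approx(210.0, abs=1 / 30.0)
    # 25 fps track and 30 Hz signal stay aligned over the same wall-clock span
    assert track.duration_s == pytest.approx(sig.duration_s, abs=1 / 25.0)
    assert track.n_frames / sig.n_samples == pytest.approx(25 / 30, abs=0.001)


def test_trim_is_idempotent(standard_session):
    left = _anatomical(standard_session)
    sync = SyncResult(6.0, 216.0, 0.0, 0.0)
    once = trim_to_calibration(left, standard_session.left_truth, sync)
    twice = trim_to_calibration(once[0], once[1], sync)
    assert np.array_equal(once[0].x, twice[0].x)
    assert np.array_equal(once[1].labels, twice[1].labels)


def test_empty_interior_rejected(standard_session):
    left = _anatomical(standard_session)
    with pytest.raises(SyncError):
        trim_to_calibration(left, None, SyncResult(500.0, 500.001, 0.0, 0.0))
    with pytest.raises(SyncError):
        SyncResult(216.0, 6.0, 0.0, 0.0)


def test_shift_to_scene_time_directions():
    sig = make_signal(np.arange(30, dtype=float)[None, :].repeat(3, axis=0))
    fwd = shift_to_scene_time(sig, 0.1)  # 3 samples dropped
    assert fwd.n_samples == 27 and fwd.x[0] == 3.0
    back = shift_to_scene_time(sig, -0.1)  # padded with the resting sample
    assert back.n_samples == 33 and np.all(back.x[:3] == sig.x[0])


def test_full_sync_reports_drift(standard_session):
    sync = sync_session(
        _anatomical(standard_session), _anatomical(standard_session, "right")
    )
    assert sync.lag_right_vs_left_s == pytest.approx(0.5, abs=1 / 30.0)
    assert abs(sync.spot_check_drift_s) <= 2 / 30.0
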