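"""Calibration-burst detection, inter-sensor lag estimation, and trimming.

The protocol time-aligns the two wrist sensors and the video with a
"calibration movement": 3–5 fast arm flexions in front of the camera at the
start and again at the end of the session.  Here the bursts are found on the
high-pass-filtered acceleration norm (gravity removed, supra-gravity
transients kept), the right-vs-left clock lag is the argmax of the normalized
cross-correlation of the two norms inside a calibration window, and everything
recorded before the first / after the second calibration is discarded.

A second lag estimate from the closing calibration window serves as the
spot-check: its difference from the opening estimate is reported as drift but
not corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import SyncError
from .signal_io import AnnotationTrack, RawAccelSignal


@dataclass
class SyncResult:
    first_calibration_end_s: float
    second_calibration_start_s: float
    lag_right_vs_left_s: float
    spot_check_drift_s: float

    def __post_init__(self) -> None:
        if not self.first_calibration_end_s < self.second_calibration_start_s:
            raise SyncError("calibration events out of order or overlapping")


def _highpass_norm(sig: RawAccelSignal, cutoff_hz: float = 0.5) -> np.ndarray:
    sos = sps.butter(4, cutoff_hz, btype="highpass", fs=sig.sample_rate_hz, output="sos")
    return sps.sosfiltfilt(sos, sig.norm)


def detect_calibration(
    sig: RawAccelSignal,
    threshold_g: float = 1.5,
    min_bursts: int = 3,
    cluster_gap_s: float = 3.0,
    highpass_hz: float = 0.5,
) -> list[tuple[float, float]]:
    """Find calibration events: clusters of ≥ ``min_bursts`` supra-threshold
    bursts of the high-pass-filtered norm, bursts closer than
    ``cluster_gap_s`` belonging to one event.

    Returns event spans ``(start_s, end_s)`` in wall-clock time.  Raises
    :class:`SyncError` if fewer than two events are found — the session
    cannot be synchronized or trimmed.
    """
    if threshold_g <= 1.0:
        raise SyncError("threshold_g must exceed 1 g (supra-gravity transients)")
    hp = np.abs(_highpass_norm(sig, highpass_hz))
    above = hp > threshold_g
    if not above.any():
        raise SyncError("no calibration bursts found (threshold above signal amplitude?)")

    idx = np.flatnonzero(above)
    run_breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate([[idx[0]], idx[run_breaks + 1]])
    run_ends = np.concatenate([idx[run_breaks], [idx[-1]]])

    fs = sig.sample_rate_hz
    gap = cluster_gap_s * fs
    clusters: list[list[int]] = [[0]]
    for i in range(1, run_starts.size):
        if run_starts[i] - run_ends[clusters[-1][-1]] <= gap:
            clusters[-1].append(i)
        else:
            clusters.append([i])

    spans = [
        (sig.t0 + run_starts[c[0]] / fs, sig.t0 + (run_ends[c[-1]] + 1) / fs)
        for c in clusters
        if len(c) >= min_bursts
    ]
    if len(spans) < 2:
        raise SyncError(
            f"found {len(spans)} calibration event(s) with >= {min_bursts} bursts; need 2"
        )
    return spans


def estimate_lag(
    left: RawAccelSignal,
    right: RawAccelSignal,
    max_lag_s: float = 5.0,
    window: tuple[float, float] | None = None,
    highpass_hz: float = 0.5,
    min_peak_corr: float = 0.6,
) -> float:
    """Lag of the right sensor relative to the left, in seconds, at sample
    resolution: the argmax of the normalized cross-correlation of the
    high-pass-filtered norms over ±``max_lag_s``.

    Positive lag = the right stream records each event later.  A flat signal
    has no correlation peak; an argmax pinned to the search boundary, or a
    best in-range correlation below ``min_peak_corr``, means the true shift
    likely exceeds ``max_lag_s`` — all three raise :class:`SyncError`.
    """
    if left.sample_rate_hz != right.sample_rate_hz:
        raise SyncError("sample rates differ between sensors")
    fs = left.sample_rate_hz
    if window is not None:
        w0, w1 = window[0] - max_lag_s, window[1] + max_lag_s
        left = left.slice_seconds(w0, w1)
        right = right.slice_seconds(w0, w1)
    a = _highpass_norm(left, highpass_hz)
    b = _highpass_norm(right, highpass_hz)
    n = min(a.size, b.size)
    a, b = a[:n] - a[:n].mean(), b[:n] - b[:n].mean()
    denom = np.sqrt(np.sum(a**2) * np.sum(b**2))
    if not np.isfinite(denom) or denom < 1e-12:
        raise SyncError("flat signal: lag undefined")

    max_lag = int(round(max_lag_s * fs))
    corr = sps.correlate(b, a, mode="full") / denom
    lags = np.arange(-(n - 1), n)
    keep = np.abs(lags) <= max_lag
    corr, lags = corr[keep], lags[keep]
    best = int(np.argmax(corr))
    if best in (0, lags.size - 1):
        raise SyncError(f"correlation peak at the ±{max_lag_s} s search boundary")
    if corr[best] < min_peak_corr:
        raise SyncError(
            f"best correlation within ±{max_lag_s} s is only {corr[best]:.2f} "
            f"(< {min_peak_corr}): true shift likely beyond the search boundary"
        )
    return float(lags[best] / fs)


def shift_to_scene_time(sig: RawAccelSignal, lag_s: float) -> RawAccelSignal:
    """Undo a clock lag: sample ``i`` of the result estimates scene time
    ``t0 + i/fs``.  Positive lag drops leading samples; negative lag pads the
    front with the first (resting) sample."""
    from dataclasses import replace

    k = int(round(lag_s * sig.sample_rate_hz))
    if k == 0:
        return sig
    if k > 0:
        return replace(sig, x=sig.x[k:].copy(), y=sig.y[k:].copy(), z=sig.z[k:].copy())
    pad = -k
    return replace(
        sig,
        x=np.concatenate([np.full(pad, sig.x[0]), sig.x]),
        y=np.concatenate([np.full(pad, sig.y[0]), sig.y]),
        z=np.concatenate([np.full(pad, sig.z[0]), sig.z]),
    )


def sync_session(
    left: RawAccelSignal,
    right: RawAccelSignal,
    threshold_g: float = 1.5,
    min_bursts: int = 3,
    max_lag_s: float = 5.0,
) -> SyncResult:
    """Full synchronization: detect the two calibration events on the left
    sensor, estimate the right-vs-left lag in the opening event's window, and
    spot-check it in the closing window."""
    spans = detect_calibration(left, threshold_g=threshold_g, min_bursts=min_bursts)
    first, last = spans[0], spans[-1]
    lag1 = estimate_lag(left, right, max_lag_s=max_lag_s, window=first)
    lag2 = estimate_lag(left, right, max_lag_s=max_lag_s, window=last)
    return SyncResult(
        first_calibration_end_s=first[1],
        second_calibration_start_s=last[0],
        lag_right_vs_left_s=lag1,
        spot_check_drift_s=lag2 - lag1,
    )


def trim_to_calibration(
    sig: RawAccelSignal,
    track: AnnotationTrack | None,
    sync: SyncResult,
) -> tuple[RawAccelSignal, AnnotationTrack | None]:
    """Keep only [first calibration end, second calibration start); signal and
    annotation track are cut at the same wall-clock boundaries so they remain
    aligned.  Idempotent: re-trimming an already-trimmed pair is the identity."""
    t0, t1 = sync.first_calibration_end_s, sync.second_calibration_start_s
    out_sig = sig.slice_seconds(t0, t1)
    if out_sig.n_samples == 0:
        raise SyncError("empty interior between calibration events")
    out_track = track.slice_seconds(t0, t1) if track is not None else None
    return out_sig, out_track
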