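"""Synthetic bilateral wrist-accelerometer sessions with ground-truth annotation.

Real recordings of the home-monitoring protocol cannot be shared, so every
downstream stage is validated on simulated sessions that emulate the protocol:
a calibration movement (3–5 fast arm flexions) at the start and end, blocks of
functional activities of daily living, walking between task locations, and
quiet sitting during conversation breaks.

The signal model is deliberately simple but class-overlapping:

* gravity of 1 g along the anatomical vertical (x) axis — the arm hangs;
* ``quiet_sitting`` — gravity plus sensor noise only;
* ``walking`` — ~1 Hz arm-swing sinusoid on the anterior–posterior (z) axis
  (antiphase between the two arms) with a small vertical bounce, plus sporadic
  sub-second multi-axis "incidental" transients (catching a rail, adjusting
  clothes).  These transients keep the non-functional class heterogeneous, so a
  classifier trained on these sessions overpredicts functional use — the
  regime observed with real home recordings — instead of being trivially
  perfect;
* ``functional_bout`` — band-limited (0.5–3 Hz) sum-of-sinusoids movement on
  all three axes under an on/off task envelope, correlated between wrists
  (most daily tasks are bimanual) with independent per-wrist jitter;
* ``calibration`` — 3–5 high-amplitude (≈2.5 g) half-sine flexion bursts.

All waveforms are continuous-time closures, so the right sensor's clock lag is
applied by evaluating the same scene at shifted times — exactly what a
free-running second device does.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .signal_io import (
    LABEL_FUNCTIONAL,
    AnnotationTrack,
    RawAccelSignal,
    to_native,
    track_to_markers,
    write_accel_csv,
    write_markers_csv,
)

ACTIVITY_KINDS = ("calibration", "functional_bout", "walking", "quiet_sitting")

#: FAABOS-style category per simulated activity kind: calibration is
#: "unknown" (0), walking and quiet sitting are non-functional (1),
#: task bouts are functional (2).
CATEGORY_FOR_KIND = {
    "calibration": 0,
    "walking": 1,
    "quiet_sitting": 1,
    "functional_bout": 2,
}

_GRAVITY = np.array([1.0, 0.0, 0.0])  # anatomical frame, arm hanging


@dataclass
class SessionConfig:
    """Parameters of one simulated session.

    ``activity_schedule`` is the full ordered list of ``(kind, duration_s)``
    blocks; the standard protocol begins and ends with a calibration block.
    ``clock_offset_s`` is the lag of the right sensor's clock relative to the
    left sensor / video time: a positive offset makes every event appear
    ``clock_offset_s`` later in the right stream.
    """

    activity_schedule: list[tuple[str, float]]
    sample_rate_hz: float = 30.0
    frame_rate_fps: float = 25.0
    clock_offset_s: float = 0.0
    noise_sd_g: float = 0.01
    seed: int = 0
    #: With incidental movement on (the realistic default), quiet sitting
    #: includes fidgeting and conversational gesticulation and walking
    #: includes brief incidental transients.  Off gives idealized blocks:
    #: sitting is pure gravity, walking is the bare arm swing — useful for
    #: physics sanity checks and clean-room tests.
    incidental_movement: bool = True

    def __post_init__(self) -> None:
        if not self.activity_schedule:
            raise ConfigurationError("activity_schedule is empty")
        for kind, dur in self.activity_schedule:
            if kind not in ACTIVITY_KINDS:
                raise ConfigurationError(f"unknown activity kind {kind!r}")
            if dur <= 0:
                raise ConfigurationError(f"non-positive duration for {kind!r}: {dur}")
        if self.sample_rate_hz <= 0:
            raise ConfigurationError("sample_rate_hz must be positive")
        if self.noise_sd_g < 0:
            raise ConfigurationError("noise_sd_g must be non-negative")

    @property
    def duration_s(self) -> float:
        return float(sum(d for _, d in self.activity_schedule))

    @property
    def block_starts(self) -> np.ndarray:
        durs = np.array([d for _, d in self.activity_schedule], dtype=float)
        return np.concatenate([[0.0], np.cumsum(durs)[:-1]])


@dataclass
class SyntheticSession:
    """Simulated bilateral recording plus per-side ground-truth tracks."""

    left: RawAccelSignal
    right: RawAccelSignal
    left_truth: AnnotationTrack
    right_truth: AnnotationTrack
    config: SessionConfig


def standard_schedule(rng: np.random.Generator | None = None, scale: float = 1.0) -> list[tuple[str, float]]:
    """A compressed version of the home protocol: calibration at both ends,
    three functional task bouts separated by walking and seated conversation.

    ``scale`` stretches the non-calibration blocks; ``rng`` adds ±20 %
    per-block jitter so cohort sessions differ in composition.
    """
    base = [
        ("calibration", 6.0),
        ("quiet_sitting", 40.0),
        ("functional_bout", 60.0),
        ("walking", 30.0),
        ("quiet_sitting", 30.0),
        ("functional_bout", 50.0),
        ("walking", 30.0),
        ("functional_bout", 40.0),
        ("quiet_sitting", 30.0),
        ("calibration", 6.0),
    ]
    out = []
    for kind, dur in base:
        if kind != "calibration":
            jitter = rng.uniform(0.8, 1.2) if rng is not None else 1.0
            dur = dur * scale * jitter
        out.append((kind, float(dur)))
    return out


# ---------------------------------------------------------------------------
# Continuous-time block waveforms


class _Block:
    def eval(self, t: np.ndarray, side: str) -> np.ndarray:  # (3, n) in g
        raise NotImplementedError


def _draw_transients(
    duration_s: float,
    rng: np.random.Generator,
    gap_range: tuple[float, float],
    amp_range: tuple[float, float],
) -> dict[str, list[tuple[float, float, np.ndarray, np.ndarray]]]:
    """Sporadic incidental movements (fidgeting, catching a rail, adjusting
    clothes): brief multi-axis bursts, independent per wrist.  These are
    annotated non-functional, yet spectrally resemble task movement — they
    are what makes the non-functional class hard and drives the classifier's
    false positives."""
    out: dict[str, list] = {}
    for side in ("left", "right"):
        events = []
        t_next = rng.uniform(*gap_range) * 0.5
        while t_next < duration_s - 1.0:
            width = rng.uniform(0.8, 2.0)
            amps = rng.uniform(*amp_range, 3)
            freqs = rng.uniform(1.0, 3.0, 3)
            events.append((t_next, width, amps, freqs))
            t_next += rng.uniform(*gap_range)
        out[side] = events
    return out


def _eval_transients(events, t: np.ndarray) -> np.ndarray:
    out = np.zeros((3, t.size))
    for t0, width, amps, freqs in events:
        u = (t - t0) / width
        inside = (u >= 0) & (u <= 1)
        if not inside.any():
            continue
        window = np.where(inside, np.sin(np.pi * np.clip(u, 0, 1)), 0.0)
        for ax in range(3):
            out[ax] += amps[ax] * window * np.sin(2 * np.pi * freqs[ax] * t)
    return out


class _Quiet(_Block):
    """Seated conversation: stillness, occasional fidgeting, and stretches of
    gesticulation.

    Gesticulation is the deliberate overlap between the classes: it is
    annotated non-functional (no object or task involvement) yet it is drawn
    from the same band-limited multi-axis waveform family, at the same
    intensity, as task movement — per-epoch features cannot tell the two
    apart.  These epochs are the ones a feature classifier systematically
    misreads as functional: the false-positive supply behind the method's
    characteristic overestimation of functional time."""

    def __init__(self, duration_s: float, rng: np.random.Generator, incidental: bool = True):
        if not incidental:
            self.transients = {"left": [], "right": []}
            self.gestures = {"left": [], "right": []}
            return
        self.transients = _draw_transients(duration_s, rng, (8.0, 16.0), (0.15, 0.4))
        self.gestures = {}
        for side in ("left", "right"):
            events = []
            t_next = rng.uniform(2.0, 8.0)
            while t_next < duration_s - 2.0:
                dur = rng.uniform(6.0, 12.0)
                freqs = rng.uniform(0.5, 3.0, 6)
                rms = rng.uniform(0.26, 0.40, 3)
                amp = rms[:, None] * np.sqrt(2.0 / 6) * rng.uniform(0.85, 1.15, (3, 6))
                phase = rng.uniform(0, 2 * np.pi, (3, 6))
                events.append((t_next, dur, freqs, amp, phase))
                t_next += dur + rng.uniform(8.0, 18.0)
            self.gestures[side] = events

    def eval(self, t, side):
        out = _eval_transients(self.transients[side], t)
        for t0, dur, freqs, amp, phase in self.gestures[side]:
            inside = (t >= t0) & (t < t0 + dur)
            if not inside.any():
                continue
            ti = t[inside]
            arg = 2 * np.pi * freqs[None, :, None] * ti[None, None, :] + phase[:, :, None]
            out[:, inside] += (amp[:, :, None] * np.sin(arg)).sum(axis=1)
        return out


class _Calibration(_Block):
    """3–5 half-sine flexion bursts, mostly on the vertical axis."""

    def __init__(self, duration_s: float, rng: np.random.Generator):
        self.n_bursts = int(rng.integers(3, 6))
        spacing = (duration_s - 1.6) / max(self.n_bursts - 1, 1)
        self.centers = 0.8 + np.arange(self.n_bursts) * spacing
        self.centers += rng.uniform(-0.08, 0.08, self.n_bursts)
        self.width = 0.35
        self.amp = rng.uniform(2.3, 2.7)

    def eval(self, t, side):
        out = np.zeros((3, t.size))
        for c in self.centers:
            u = (t - (c - self.width / 2)) / self.width
            inside = (u >= 0) & (u <= 1)
            pulse = np.where(inside, np.sin(np.pi * np.clip(u, 0, 1)), 0.0)
            out[0] += self.amp * pulse
            out[2] += 0.5 * self.amp * pulse
        return out


class _Walking(_Block):
    """~1 Hz arm swing (antiphase across arms) + sporadic incidental transients."""

    def __init__(self, duration_s: float, rng: np.random.Generator, incidental: bool = True):
        self.f = rng.uniform(0.9, 1.1)
        self.amp = rng.uniform(0.12, 0.18)
        self.phase = rng.uniform(0, 2 * np.pi)
        self.transients = (
            _draw_transients(duration_s, rng, (4.0, 9.0), (0.25, 0.55))
            if incidental
            else {"left": [], "right": []}
        )

    def eval(self, t, side):
        out = np.zeros((3, t.size))
        phase = self.phase + (np.pi if side == "right" else 0.0)
        out[2] = self.amp * np.sin(2 * np.pi * self.f * t + phase)
        out[0] = 0.03 * np.sin(4 * np.pi * self.f * t + phase)
        return out + _eval_transients(self.transients[side], t)


class _Functional(_Block):
    """Band-limited multi-axis task movement under an on/off envelope,
    shared between wrists with independent per-wrist jitter."""

    _K = 8

    def __init__(self, duration_s: float, rng: np.random.Generator):
        self.freqs = rng.uniform(0.5, 3.0, self._K)
        rms = rng.uniform(0.26, 0.40, 3)
        # slow within-bout intensity modulation: every task alternates gentler
        # and more vigorous stretches instead of being uniformly gentle
        self.mod_period = rng.uniform(15.0, 30.0)
        self.mod_phase = rng.uniform(0, 2 * np.pi)
        base_amp = rms[:, None] * np.sqrt(2.0 / self._K)  # (3, K)
        self.params = {}
        for side in ("left", "right"):
            amp = base_amp * rng.uniform(0.85, 1.15, (3, self._K))
            phase = rng.uniform(0, 2 * np.pi, (3, self._K))
            self.params[side] = (amp, phase)
        # on/off task envelope: brief pauses (0.3–1 s) between 4–9 s active
        # stretches — tasks are annotated functional across micro-pauses, so
        # pauses stay short relative to the 4-s epoch
        switches = [0.0]
        t_cur, on = 0.0, True
        while t_cur < duration_s:
            t_cur += rng.uniform(4.0, 9.0) if on else rng.uniform(0.3, 1.0)
            switches.append(min(t_cur, duration_s))
            on = not on
        self.switches = np.array(switches)

    def _envelope(self, t):
        seg = np.searchsorted(self.switches, t, side="right") - 1
        return (seg % 2 == 0).astype(float)  # even segments are "on"

    def eval(self, t, side):
        amp, phase = self.params[side]
        arg = 2 * np.pi * self.freqs[None, :, None] * t[None, None, :] + phase[:, :, None]
        out = (amp[:, :, None] * np.sin(arg)).sum(axis=1)
        mod = 1.05 + 0.2 * np.sin(2 * np.pi * t / self.mod_period + self.mod_phase)
        return out * (self._envelope(t) * mod)[None, :]


def _build_block(kind: str, dur: float, rng: np.random.Generator, incidental: bool) -> _Block:
    if kind == "calibration":
        return _Calibration(dur, rng)
    if kind == "functional_bout":
        return _Functional(dur, rng)
    if kind == "walking":
        return _Walking(dur, rng, incidental)
    return _Quiet(dur, rng, incidental)


class _Scene:
    """The continuous-time session: gravity plus per-block movement."""

    def __init__(self, config: SessionConfig, rng: np.random.Generator):
        self.starts = config.block_starts
        self.durations = np.array([d for _, d in config.activity_schedule])
        self.blocks = [
            _build_block(kind, float(dur), rng, config.incidental_movement)
            for kind, dur in config.activity_schedule
        ]
        self.total = config.duration_s

    def eval(self, t: np.ndarray, side: str) -> np.ndarray:
        out = np.tile(_GRAVITY[:, None], (1, t.size))
        idx = np.clip(np.searchsorted(self.starts, t, side="right") - 1, 0, len(self.blocks) - 1)
        in_session = (t >= 0) & (t < self.total)
        for b, block in enumerate(self.blocks):
            sel = in_session & (idx == b)
            if sel.any():
                out[:, sel] += block.eval(t[sel] - self.starts[b], side)
        return out


def simulate_session(config: SessionConfig) -> SyntheticSession:
    """Simulate one bilateral session.

    Deterministic for a fixed ``config.seed``.  Signals are returned in the
    device-native convention (what a strapped-on sensor would record); pass
    them through :func:`armuse.signal_io.to_anatomical` as with real data.
    The right stream lags the scene by ``clock_offset_s``; the truth tracks
    are in scene (video) time for both sides.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_scene, rng_noise_l, rng_noise_r = (np.random.default_rng(s) for s in ss.spawn(3))
    scene = _Scene(config, rng_scene)

    fs = config.sample_rate_hz
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs

    signals = {}
    for side, t_eval, rng_noise in (
        ("left", t, rng_noise_l),
        ("right", t - config.clock_offset_s, rng_noise_r),
    ):
        xyz = scene.eval(t_eval, side)
        if config.noise_sd_g > 0:
            xyz = xyz + rng_noise.normal(0.0, config.noise_sd_g, xyz.shape)
        anatomical = RawAccelSignal(
            t0=0.0, sample_rate_hz=fs, x=xyz[0], y=xyz[1], z=xyz[2],
            side=side, convention="anatomical",
        )
        signals[side] = to_native(anatomical)

    track = _truth_track(config)
    return SyntheticSession(
        left=signals["left"],
        right=signals["right"],
        left_truth=track,
        right_truth=AnnotationTrack(track.frame_rate_fps, track.labels.copy()),
        config=config,
    )


def _truth_track(config: SessionConfig) -> AnnotationTrack:
    n_frames = int(round(config.duration_s * config.frame_rate_fps))
    centers = (np.arange(n_frames) + 0.5) / config.frame_rate_fps
    idx = np.clip(
        np.searchsorted(config.block_starts, centers, side="right") - 1,
        0,
        len(config.activity_schedule) - 1,
    )
    cats = np.array([CATEGORY_FOR_KIND[kind] for kind, _ in config.activity_schedule], dtype=np.int8)
    return AnnotationTrack(frame_rate_fps=config.frame_rate_fps, labels=cats[idx])


def truth_functional_minutes(session: SyntheticSession, side: str, epoch_len_s: float = 4.0) -> float:
    """Total functional minutes from the ground-truth track: the number of
    epochs whose strict-majority label is functional, times the epoch length."""
    from .annotation import frames_to_epochs  # local import avoids a cycle

    track = session.left_truth if side == "left" else session.right_truth
    series = frames_to_epochs(track, epoch_len_s=epoch_len_s)
    n_functional = int(np.sum(series.labels == LABEL_FUNCTIONAL))
    return n_functional * epoch_len_s / 60.0


def write_session(session: SyntheticSession, directory: str | Path) -> dict[str, Path]:
    """Emit the session in the same CSV dialect real exports use: one
    acceleration CSV per wrist plus one timeline-marker CSV for both sides."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "left": directory / "accel_left.csv",
        "right": directory / "accel_right.csv",
        "markers": directory / "markers.csv",
    }
    write_accel_csv(session.left, paths["left"])
    write_accel_csv(session.right, paths["right"])
    import pandas as pd

    markers = pd.concat(
        [
            track_to_markers(session.left_truth, "left"),
            track_to_markers(session.right_truth, "right"),
        ],
        ignore_index=True,
    )
    write_markers_csv(markers, paths["markers"], session.left_truth.frame_rate_fps)
    return paths
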