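import numpy as np
import pytest

from armuse.signal_io import RawAccelSignal
from armuse.synthetic_session import SessionConfig, simulate_session


@pytest.fixture
def quiet_session():
    """Noise-free, movement-free session: every sample has unit norm."""
    cfg = SessionConfig(
        [("quiet_sitting", 20.0)], noise_sd_g=0.0, seed=7, incidental_movement=False
    )
    return simulate_session(cfg)


@pytest.fixture
def standard_session():
    """One full protocol session with calibration at both ends and a 0.5 s
    right-sensor clock lag."""
    schedule = [
        ("calibration", 6.0),
        ("quiet_sitting", 40.0),
        ("functional_bout", 60.0),
        ("walking", 30.0),
        ("quiet_sitting", 30.0),
        ("functional_bout", 50.0),
        ("calibration", 6.0),
    ]
    cfg = SessionConfig(schedule, clock_offset_s=0.5, seed=11)
    return simulate_session(cfg)


def counts_probe_signal(i: int, duration_s: float = 30.0) -> RawAccelSignal:
    """Deterministic 30 Hz probe signal #i for the counts-conversion
    regression suite: gravity plus a three-tone mixture with noise, except
    probe 10 which is the pure 1.5 Hz, 0.5 g test tone."""
    n = int(duration_s * 30)
    t = np.arange(n) / 30.0
    if i == 10:
        x = np.ones(n)
        y = 0.5 * np.sin(2 * np.pi * 1.5 * t)
        z = np.zeros(n)
    else:
        rng = np.random.default_rng(8600 + i)
        amps = rng.uniform(0.05, 0.6, 3)
        freqs = rng.uniform(0.3, 5.0, 3)
        phases = rng.uniform(0, 2 * np.pi, 3)
        axes = [
            a * np.sin(2 * np.pi * f * t + p) + rng.normal(0, 0.05, n)
            for a, f, p in zip(amps, freqs, phases)
        ]
        x, y, z = axes[0] + 1.0, axes[1], axes[2]
    return RawAccelSignal(
        t0=0.0, sample_rate_hz=30.0, x=x, y=y, z=z, side="left", convention="anatomical"
    )


def make_signal(xyz: np.ndarray, fs: float = 30.0, side: str = "left",
                convention: str = "anatomical", t0: float = 0.0) -> RawAccelSignal:
    xyz = np.asarray(xyz, dtype=float)
    return RawAccelSignal(
        t0=t0, sample_rate_hz=fs, x=xyz[0], y=xyz[1], z=xyz[2],
        side=side, convention=convention,
    )
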