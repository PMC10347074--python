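"""Interchange I/O for raw tri-axial wrist acceleration and frame-level annotations.

Acceleration travels as plain CSV (``time,x,y,z``; seconds and g) with a small
``#``-prefixed metadata header, so the pipeline never depends on a proprietary
device container.  Sensor axes arrive in the device-native frame and are mapped
into the anatomical frame used throughout the pipeline:

* ``x`` — vertical axis, in line with the forearm, cranial direction positive;
* ``y`` — medio-lateral axis, pointing medially for the right hand and
  laterally for the left hand (the two wrists are mirror images);
* ``z`` — anterior–posterior axis, anterior positive.

The native→anatomical transform is always a signed permutation (an isometry:
each anatomical axis is ± one native axis), configured by a named mounting map
because wrist-worn devices differ only in how the case is strapped on.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParseError

LABEL_UNKNOWN = 0
LABEL_NON_FUNCTIONAL = 1
LABEL_FUNCTIONAL = 2

_ACCEL_COLUMNS = ("time", "x", "y", "z")
_MARKER_COLUMNS = ("start_s", "end_s", "side", "category")


@dataclass
class RawAccelSignal:
    """A tri-axial acceleration stream from one wrist.

    Attributes
    ----------
    t0 : float
        Wall-clock start time of the first sample, seconds.
    sample_rate_hz : float
        Sampling rate; 30 Hz native, 50 Hz after resampling.
    x, y, z : ndarray
        Per-sample acceleration in g, equal length.
    side : {"left", "right"}
    convention : {"native", "anatomical"}
    """

    t0: float
    sample_rate_hz: float
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    side: str
    convention: str = "native"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (self.x.shape == self.y.shape == self.z.shape):
            raise ConfigurationError("x, y, z must have equal length")
        if self.sample_rate_hz <= 0:
            raise ConfigurationError("sample_rate_hz must be positive")
        if self.side not in ("left", "right"):
            raise ConfigurationError(f"unknown side {self.side!r}")
        if self.convention not in ("native", "anatomical"):
            raise ConfigurationError(f"unknown convention {self.convention!r}")

    @property
    def n_samples(self) -> int:
        return self.x.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sample_rate_hz

    @property
    def norm(self) -> np.ndarray:
        """Per-sample Euclidean norm (vector magnitude) in g."""
        return np.sqrt(self.x**2 + self.y**2 + self.z**2)

    def slice_seconds(self, start_s: float, stop_s: float) -> "RawAccelSignal":
        """Samples with wall-clock time in [start_s, stop_s)."""
        i0 = int(np.ceil(round((start_s - self.t0) * self.sample_rate_hz, 9)))
        i1 = int(np.ceil(round((stop_s - self.t0) * self.sample_rate_hz, 9)))
        i0, i1 = max(i0, 0), min(max(i1, 0), self.n_samples)
        return replace(
            self,
            t0=self.t0 + i0 / self.sample_rate_hz,
            x=self.x[i0:i1].copy(),
            y=self.y[i0:i1].copy(),
            z=self.z[i0:i1].copy(),
        )


@dataclass
class AnnotationTrack:
    """Per-frame categorical labels at a fixed frame rate.

    Categories: 0 unknown (includes the calibration procedure), 1
    non-functional (arm swing while walking, quiet sitting), 2 functional
    (task-specific arm movement).
    """

    frame_rate_fps: float
    labels: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        bad = ~np.isin(self.labels, (LABEL_UNKNOWN, LABEL_NON_FUNCTIONAL, LABEL_FUNCTIONAL))
        if bad.any():
            raise ConfigurationError(
                f"annotation labels must be 0/1/2; first bad frame {int(np.argmax(bad))}"
            )

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_fps

    def slice_seconds(self, start_s: float, stop_s: float) -> "AnnotationTrack":
        i0 = int(np.ceil(round((start_s - self.t0) * self.frame_rate_fps, 9)))
        i1 = int(np.ceil(round((stop_s - self.t0) * self.frame_rate_fps, 9)))
        i0, i1 = max(i0, 0), min(max(i1, 0), self.n_frames)
        return AnnotationTrack(
            frame_rate_fps=self.frame_rate_fps,
            labels=self.labels[i0:i1].copy(),
            t0=self.t0 + i0 / self.frame_rate_fps,
        )


# ---------------------------------------------------------------------------
# Mounting maps: anatomical axis -> (native axis, sign), per side.
#
# Default: device x points distally along the forearm (so cranial = -x),
# device z points anteriorly out of the watch face for both wrists, and the
# medio-lateral direction mirrors between wrists.
MOUNTING_MAPS: dict[str, dict[str, dict[str, tuple[str, int]]]] = {
    "wrist_default": {
        "right": {"x": ("x", -1), "y": ("y", +1), "z": ("z", +1)},
        "left": {"x": ("x", -1), "y": ("y", -1), "z": ("z", +1)},
    },
}

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


def mounting_matrix(mounting: str, side: str) -> np.ndarray:
    """3×3 signed-permutation matrix M with a_anatomical = M @ a_native."""
    try:
        axis_map = MOUNTING_MAPS[mounting][side]
    except KeyError:
        raise ConfigurationError(f"unknown mounting map {mounting!r} for side {side!r}") from None
    m = np.zeros((3, 3))
    for anat_axis, (native_axis, sign) in axis_map.items():
        m[_AXIS_INDEX[anat_axis], _AXIS_INDEX[native_axis]] = sign
    return m


def to_anatomical(signal: RawAccelSignal, mounting: str = "wrist_default") -> RawAccelSignal:
    """Remap a native-convention signal into the anatomical frame.

    The transform is a signed permutation, so the per-sample Euclidean norm is
    preserved exactly.  Applying it to an already-anatomical signal is an error.
    """
    if signal.convention != "native":
        raise ConfigurationError("to_anatomical expects a native-convention signal")
    m = mounting_matrix(mounting, signal.side)
    xyz = m @ np.vstack([signal.x, signal.y, signal.z])
    return replace(signal, x=xyz[0], y=xyz[1], z=xyz[2], convention="anatomical")


def to_native(signal: RawAccelSignal, mounting: str = "wrist_default") -> RawAccelSignal:
    """Inverse of :func:`to_anatomical` (signed permutations are orthogonal)."""
    if signal.convention != "anatomical":
        raise ConfigurationError("to_native expects an anatomical-convention signal")
    m = mounting_matrix(mounting, signal.side).T
    xyz = m @ np.vstack([signal.x, signal.y, signal.z])
    return replace(signal, x=xyz[0], y=xyz[1], z=xyz[2], convention="native")


# ---------------------------------------------------------------------------
# CSV interchange


def write_accel_csv(signal: RawAccelSignal, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# armuse accel csv v1\n")
        fh.write(f"# sample_rate_hz={signal.sample_rate_hz!r}\n")
        fh.write(f"# side={signal.side}\n")
        fh.write(f"# convention={signal.convention}\n")
        fh.write(f"# t0={signal.t0!r}\n")
        df = pd.DataFrame(
            {"time": signal.times, "x": signal.x, "y": signal.y, "z": signal.z}
        )
        # default float repr is shortest-roundtrip -> write/read is lossless
        df.to_csv(fh, index=False)


def _read_meta(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def read_accel_csv(path: str | Path, side: str | None = None) -> RawAccelSignal:
    """Read an acceleration CSV written in the package interchange dialect.

    The header metadata declares sample rate, side and convention; ``side``
    overrides the header when given.  Any NaN or non-numeric cell is a
    :class:`ParseError` naming the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    meta = _read_meta(path)
    if "sample_rate_hz" not in meta:
        raise ParseError(f"{path}: header does not declare sample_rate_hz")
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message is good enough
        raise ParseError(f"{path}: {exc}") from exc
    for col in _ACCEL_COLUMNS:
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    numeric = df[list(_ACCEL_COLUMNS)].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        row = int(bad.idxmax())
        raise ParseError(f"{path}: non-numeric or missing value at data row {row}")
    return RawAccelSignal(
        t0=float(meta.get("t0", numeric["time"].iloc[0])),
        sample_rate_hz=float(meta["sample_rate_hz"]),
        x=numeric["x"].to_numpy(),
        y=numeric["y"].to_numpy(),
        z=numeric["z"].to_numpy(),
        side=side or meta.get("side", "left"),
        convention=meta.get("convention", "native"),
    )


def write_markers_csv(markers: pd.DataFrame, path: str | Path, frame_rate_fps: float = 25.0) -> None:
    """Write a timeline-marker table (columns ``start_s,end_s,side,category``)."""
    path = Path(path)
    for col in _MARKER_COLUMNS:
        if col not in markers.columns:
            raise ParseError(f"marker table missing column {col!r}")
    with path.open("w") as fh:
        fh.write("# armuse annotation markers v1\n")
        fh.write(f"# frame_rate_fps={frame_rate_fps!r}\n")
        markers[list(_MARKER_COLUMNS)].to_csv(fh, index=False, float_format="%.9g")


def read_markers_csv(path: str | Path) -> tuple[pd.DataFrame, float]:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    meta = _read_meta(path)
    df = pd.read_csv(path, comment="#")
    for col in _MARKER_COLUMNS:
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    return df, float(meta.get("frame_rate_fps", 25.0))


def markers_to_track(
    markers: pd.DataFrame,
    side: str,
    duration_s: float,
    frame_rate_fps: float = 25.0,
    default_category: int = LABEL_NON_FUNCTIONAL,
) -> AnnotationTrack:
    """Rasterise timeline markers for one side into a per-frame track.

    Frames not covered by any marker get ``default_category`` (non-functional:
    the annotator marks functional spans and the calibration, everything else
    is incidental movement or stillness).  Later markers overwrite earlier ones.
    """
    n_frames = int(round(duration_s * frame_rate_fps))
    labels = np.full(n_frames, default_category, dtype=np.int8)
    sel = markers[markers["side"] == side]
    for row in sel.itertuples(index=False):
        i0 = max(int(np.floor(row.start_s * frame_rate_fps + 1e-9)), 0)
        i1 = min(int(np.floor(row.end_s * frame_rate_fps + 1e-9)), n_frames)
        labels[i0:i1] = int(row.category)
    return AnnotationTrack(frame_rate_fps=frame_rate_fps, labels=labels)


def track_to_markers(track: AnnotationTrack, side: str) -> pd.DataFrame:
    """Run-length encode a track into a timeline-marker table (all categories)."""
    labels = track.labels
    if labels.size == 0:
        return pd.DataFrame(columns=list(_MARKER_COLUMNS))
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    return pd.DataFrame(
        {
            "start_s": track.t0 + starts / track.frame_rate_fps,
            "end_s": track.t0 + ends / track.frame_rate_fps,
            "side": side,
            "category": labels[starts].astype(int),
        }
    )
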