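"""Frame-level annotation → per-epoch labels → binary ground truth.

The video annotation is a per-frame stream (25 fps) of three categories:
0 unknown (calibration etc.), 1 non-functional, 2 functional.  Evaluation and
classification work on non-overlapping 4-s epochs (100 frames at 25 fps): an
epoch takes the category held by a *strict majority* (>50 %) of its frames,
otherwise it is ``mixed``.  Unknown-majority epochs are discarded from the
binary ground truth; mixed epochs are handled by a configurable policy
(excluded by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .signal_io import (
    LABEL_FUNCTIONAL,
    LABEL_NON_FUNCTIONAL,
    LABEL_UNKNOWN,
    AnnotationTrack,
)

#: Epoch-level label codes.  0/1/2 reuse the frame categories; 3 marks an
#: epoch with no strict-majority category.
EPOCH_UNKNOWN = LABEL_UNKNOWN
EPOCH_NON_FUNCTIONAL = LABEL_NON_FUNCTIONAL
EPOCH_FUNCTIONAL = LABEL_FUNCTIONAL
EPOCH_MIXED = 3

EPOCH_LABEL_NAMES = {
    EPOCH_UNKNOWN: "unknown",
    EPOCH_NON_FUNCTIONAL: "non_functional",
    EPOCH_FUNCTIONAL: "functional",
    EPOCH_MIXED: "mixed",
}

MIXED_POLICIES = ("exclude", "as_functional", "as_nonfunctional")


@dataclass
class EpochLabelSeries:
    """Per-epoch labels plus the derived binary ground truth.

    ``binary`` holds 1 (functional) / 0 (non-functional) for *retained*
    epochs only; ``retained_index[i]`` is the original epoch position of
    ``binary[i]``.
    """

    epoch_len_s: float
    labels: np.ndarray
    binary: np.ndarray
    retained_index: np.ndarray
    mixed_policy: str = "exclude"

    @property
    def n_epochs(self) -> int:
        return self.labels.shape[0]

    def functional_minutes(self) -> float:
        """Sum of time spent functional, from the binary truth."""
        return float(np.sum(self.binary == 1)) * self.epoch_len_s / 60.0


def frames_to_epochs(
    track: AnnotationTrack,
    epoch_len_s: float = 4.0,
    mixed_policy: str = "exclude",
) -> EpochLabelSeries:
    """Tile the track into epochs from its start and label each by strict
    majority; the trailing partial epoch is dropped.

    Raises
    ------
    ConfigurationError
        If the track is shorter than one epoch or the frame count per epoch
        is not integral (25 fps × 4 s = 100 frames).
    """
    frames_per_epoch_f = track.frame_rate_fps * epoch_len_s
    frames_per_epoch = int(round(frames_per_epoch_f))
    if abs(frames_per_epoch_f - frames_per_epoch) > 1e-9 or frames_per_epoch < 1:
        raise ConfigurationError(
            f"epoch of {epoch_len_s} s is not an integral number of frames at "
            f"{track.frame_rate_fps} fps"
        )
    n_epochs = track.n_frames // frames_per_epoch
    if n_epochs == 0:
        raise ConfigurationError("track shorter than one epoch")
    frames = track.labels[: n_epochs * frames_per_epoch].reshape(n_epochs, frames_per_epoch)

    counts = np.stack(
        [np.sum(frames == cat, axis=1) for cat in (LABEL_UNKNOWN, LABEL_NON_FUNCTIONAL, LABEL_FUNCTIONAL)],
        axis=1,
    )
    winner = np.argmax(counts, axis=1)
    has_majority = counts[np.arange(n_epochs), winner] * 2 > frames_per_epoch
    labels = np.where(has_majority, winner, EPOCH_MIXED).astype(np.int8)

    binary, retained = binary_truth_from_labels(labels, mixed_policy)
    return EpochLabelSeries(
        epoch_len_s=float(epoch_len_s),
        labels=labels,
        binary=binary,
        retained_index=retained,
        mixed_policy=mixed_policy,
    )


def binary_truth_from_labels(
    labels: np.ndarray, mixed_policy: str = "exclude"
) -> tuple[np.ndarray, np.ndarray]:
    """Relabel epoch categories to binary functional(1)/non-functional(0).

    Unknown epochs are always discarded; ``mixed`` epochs follow the policy.
    Returns ``(binary, retained_index)``.
    """
    if mixed_policy not in MIXED_POLICIES:
        raise ConfigurationError(f"unknown mixed_policy {mixed_policy!r}")
    labels = np.asarray(labels)
    value_for = {
        EPOCH_FUNCTIONAL: 1,
        EPOCH_NON_FUNCTIONAL: 0,
        EPOCH_MIXED: {
            "exclude": None,
            "as_functional": 1,
            "as_nonfunctional": 0,
        }[mixed_policy],
        EPOCH_UNKNOWN: None,
    }
    binary, retained = [], []
    for i, lab in enumerate(labels):
        v = value_for[int(lab)]
        if v is not None:
            binary.append(v)
            retained.append(i)
    return np.asarray(binary, dtype=np.int8), np.asarray(retained, dtype=np.intp)


def binary_truth(series: EpochLabelSeries, mixed_policy: str = "exclude") -> np.ndarray:
    """Binary ground truth of a series under the given mixed policy."""
    binary, _ = binary_truth_from_labels(series.labels, mixed_policy)
    return binary
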