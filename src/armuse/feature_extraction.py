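"""50 Hz resampling and the 11 per-epoch features used by the classifier.

Per non-overlapping 4-s epoch (200 samples at 50 Hz) the features are the
mean and variance of each axis, plus the mean, variance, minimum, maximum and
Shannon entropy of the per-sample Euclidean norm.  Variances are population
variances (divide by n).  The entropy estimator is a 16-bin histogram over the
epoch's own norm range in bits, so a constant epoch has entropy 0 and a
uniformly bin-filling epoch has log2(16) = 4 bits; the bin count is
configurable.

Min-max scaling to [0, 1] is fit on a training corpus only and applied —
with clipping — to everything downstream, so no test-session statistics leak
into the normalization.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import replace

from scipy.interpolate import CubicSpline
from sklearn.preprocessing import MinMaxScaler

from .errors import ConfigurationError
from .signal_io import RawAccelSignal

#: Frozen feature order — the serialization contract with the classifier.
FEATURE_NAMES = (
    "mean_x", "mean_y", "mean_z",
    "var_x", "var_y", "var_z",
    "norm_mean", "norm_var", "norm_min", "norm_max",
    "norm_entropy",
)

TARGET_RATE_HZ = 50.0
DEFAULT_ENTROPY_BINS = 16


def resample_to_50hz(sig: RawAccelSignal) -> RawAccelSignal:
    """Resample a 30 Hz signal to 50 Hz by per-axis cubic spline interpolation.

    Duration is preserved to within one output sample.  A signal already at
    50 Hz passes through unchanged.
    """
    if sig.sample_rate_hz == TARGET_RATE_HZ:
        return sig
    if sig.sample_rate_hz != 30.0:
        raise ConfigurationError(f"expected 30 Hz input, got {sig.sample_rate_hz} Hz")
    if sig.n_samples < 4:
        raise ConfigurationError("need at least 4 samples for cubic spline resampling")
    t_in = np.arange(sig.n_samples) / sig.sample_rate_hz
    n_out = int(np.floor(sig.n_samples * TARGET_RATE_HZ / sig.sample_rate_hz))
    t_out = np.arange(n_out) / TARGET_RATE_HZ
    out = {}
    for name in ("x", "y", "z"):
        spline = CubicSpline(t_in, getattr(sig, name))
        out[name] = spline(t_out)
    return replace(sig, sample_rate_hz=TARGET_RATE_HZ, **out)


def shannon_entropy(values: np.ndarray, n_bins: int = DEFAULT_ENTROPY_BINS) -> float:
    """Histogram Shannon entropy in bits over the sample's own [min, max]
    range; 0·log0 ≡ 0 and a degenerate (constant) sample has entropy 0."""
    values = np.asarray(values, dtype=float)
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        return 0.0
    hist, _ = np.histogram(values, bins=n_bins, range=(lo, hi))
    p = hist / values.size
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def epoch_features(
    sig: RawAccelSignal,
    epoch_len_s: float = 4.0,
    entropy_bins: int = DEFAULT_ENTROPY_BINS,
) -> pd.DataFrame:
    """Compute the 11 features for every complete epoch.

    Epochs tile the signal from its start; a trailing partial epoch is
    dropped.  Returns one row per epoch with columns :data:`FEATURE_NAMES`
    (unscaled physical units: g and g²).
    """
    spe = int(round(sig.sample_rate_hz * epoch_len_s))
    n_epochs = sig.n_samples // spe
    if n_epochs == 0:
        raise ConfigurationError("signal shorter than one epoch")

    def split(v: np.ndarray) -> np.ndarray:
        return v[: n_epochs * spe].reshape(n_epochs, spe)

    ex, ey, ez = split(sig.x), split(sig.y), split(sig.z)
    norm = np.sqrt(ex**2 + ey**2 + ez**2)
    feats = {
        "mean_x": ex.mean(axis=1), "mean_y": ey.mean(axis=1), "mean_z": ez.mean(axis=1),
        "var_x": ex.var(axis=1), "var_y": ey.var(axis=1), "var_z": ez.var(axis=1),
        "norm_mean": norm.mean(axis=1),
        "norm_var": norm.var(axis=1),
        "norm_min": norm.min(axis=1),
        "norm_max": norm.max(axis=1),
        "norm_entropy": np.array([shannon_entropy(row, entropy_bins) for row in norm]),
    }
    return pd.DataFrame(feats, columns=list(FEATURE_NAMES))


def fit_minmax(features: pd.DataFrame) -> MinMaxScaler:
    """Fit the per-feature min-max scaler on a (training) feature matrix."""
    if len(features) == 0:
        raise ConfigurationError("cannot fit a scaler on an empty feature set")
    scaler = MinMaxScaler(clip=True)
    scaler.fit(features[list(FEATURE_NAMES)].to_numpy())
    return scaler


def apply_minmax(scaler: MinMaxScaler, features: pd.DataFrame) -> pd.DataFrame:
    """Map each feature by (v − min)/(max − min) from the fitted range,
    clipping out-of-range values to [0, 1]; a constant fitted feature maps
    to 0."""
    arr = scaler.transform(features[list(FEATURE_NAMES)].to_numpy())
    return pd.DataFrame(arr, columns=list(FEATURE_NAMES), index=features.index)
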