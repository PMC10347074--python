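"""Validation outcomes: confusion-matrix metrics, use summaries, cohort
mean differences, and tie-corrected Spearman correlation.

Seven outcomes are computed per session and side: (1) accuracy, recall,
specificity and f1 of the classifier against the video-annotation ground
truth; total functional minutes by (2) ground truth, (3) classifier and
(4) counts baseline; and the corresponding percentages of the session
functionally active (5)–(7).

The module also packages the published per-participant values of the
ten-participant home-monitoring validation cohort (demographics with
QuickDASH, per-side metrics, per-side use summaries) and recomputes their
printed summary rows — column averages, mean differences vs ground truth,
and the Spearman correlation between QuickDASH and accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .errors import ConfigurationError

SIDES = ("left", "right")
METHODS = ("ground_truth", "mlm", "counts")


@dataclass
class ConfusionMatrix:
    """Epoch counts with "functional" as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ConfigurationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsReport:
    """Fraction-valued metrics; any metric with a zero denominator is
    reported as 0.0 and its name recorded in ``degenerate`` (auditable,
    but keeps cohort averaging well-defined)."""

    accuracy: float
    recall: float
    specificity: float
    precision: float
    f1: float
    degenerate: set[str] = field(default_factory=set)


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionMatrix:
    """Count TP/FP/FN/TN over equal-length binary label sequences."""
    pred = np.asarray(pred).astype(int)
    truth = np.asarray(truth).astype(int)
    if pred.shape != truth.shape:
        raise ConfigurationError(
            f"prediction ({pred.shape}) and truth ({truth.shape}) differ in length"
        )
    return ConfusionMatrix(
        tp=int(np.sum((pred == 1) & (truth == 1))),
        fp=int(np.sum((pred == 1) & (truth == 0))),
        fn=int(np.sum((pred == 0) & (truth == 1))),
        tn=int(np.sum((pred == 0) & (truth == 0))),
    )


def _ratio(num: int, den: int, name: str, degenerate: set[str]) -> float:
    if den == 0:
        degenerate.add(name)
        return 0.0
    return num / den


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """accuracy=(TP+TN)/N, recall=TP/(TP+FN), specificity=TN/(TN+FP),
    precision=TP/(TP+FP), f1=harmonic mean of precision and recall."""
    deg: set[str] = set()
    accuracy = _ratio(cm.tp + cm.tn, cm.total, "accuracy", deg)
    recall = _ratio(cm.tp, cm.tp + cm.fn, "recall", deg)
    specificity = _ratio(cm.tn, cm.tn + cm.fp, "specificity", deg)
    precision = _ratio(cm.tp, cm.tp + cm.fp, "precision", deg)
    if precision + recall == 0:
        deg.add("f1")
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsReport(
        accuracy=accuracy,
        recall=recall,
        specificity=specificity,
        precision=precision,
        f1=f1,
        degenerate=deg,
    )


@dataclass
class UseSummary:
    """Total functional minutes and fraction of the session functionally
    active, per estimation method, for one session and side."""

    duration_s: float
    minutes: dict[str, float]
    percent: dict[str, float]


def use_summary(
    labels_by_method: dict[str, tuple[np.ndarray, float]],
    session_duration_s: float,
) -> UseSummary:
    """Summarise binary epoch labels into the minutes/percent outcomes.

    ``labels_by_method`` maps a method name to ``(binary labels, epoch_len_s)``
    — 4-s epochs for ground truth and classifier, 1-s epochs for the counts
    baseline.  Percent = functional seconds / total session seconds.
    """
    if session_duration_s <= 0:
        raise ConfigurationError("session_duration_s must be positive")
    minutes, percent = {}, {}
    for method, (labels, epoch_len_s) in labels_by_method.items():
        labels = np.asarray(labels)
        mins = float(np.sum(labels == 1)) * epoch_len_s / 60.0
        minutes[method] = mins
        percent[method] = min(mins * 60.0 / session_duration_s, 1.0)
    return UseSummary(duration_s=session_duration_s, minutes=minutes, percent=percent)


def mean_difference(
    use_table: pd.DataFrame, method: str, side: str, reference: str = "ground_truth"
) -> tuple[float, float]:
    """Cohort mean (and sample SD) of per-participant (method − reference)
    percent-functionally-active differences.

    ``use_table`` is long-form with columns
    ``participant, side, method, minutes, percent``.
    """
    wide = (
        use_table[use_table["side"] == side]
        .pivot(index="participant", columns="method", values="percent")
    )
    for col in (method, reference):
        if col not in wide.columns or wide[col].isna().any():
            missing = wide.index[wide.get(col, pd.Series(np.nan, index=wide.index)).isna()]
            raise ConfigurationError(
                f"missing {col!r} percent for participant(s): {list(missing)}"
            )
    if len(wide) < 2:
        raise ConfigurationError("need at least two participants")
    diff = wide[method] - wide[reference]
    return float(diff.mean()), float(diff.std(ddof=1))


@dataclass
class SpearmanResult:
    rho: float
    p_value: float
    degenerate: bool = False


def spearman_tied(x, y) -> SpearmanResult:
    """Tie-corrected Spearman correlation (Pearson on mid-ranks) with a
    two-sided t-approximation p-value; a constant input vector makes the
    correlation undefined and is flagged instead of raising."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigurationError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ConfigurationError("need n >= 3 for a Spearman correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(rho=float("nan"), p_value=float("nan"), degenerate=True)
    rho, p = spstats.spearmanr(x, y)
    return SpearmanResult(rho=float(rho), p_value=float(p))


# ---------------------------------------------------------------------------
# Packaged reported cohort values


def _load_fixture(name: str) -> pd.DataFrame:
    with resources.files("armuse.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, comment="#")


def load_reported_demographics() -> pd.DataFrame:
    """Per-participant demographics including the QuickDASH score."""
    return _load_fixture("reported_demographics.csv")


def load_reported_metrics() -> pd.DataFrame:
    """Per-participant, per-side printed accuracy/recall/specificity/f1."""
    return _load_fixture("reported_classifier_metrics.csv")


def load_reported_use_summary() -> pd.DataFrame:
    """Per-participant, per-side, per-method printed minutes and percent."""
    return _load_fixture("reported_use_summary.csv")


def recompute_reported_summaries() -> dict:
    """Recompute every summary statistic of the packaged cohort tables from
    the per-participant printed values: per-side column averages of the
    classifier metrics, mean differences (±SD) of percent functionally active
    vs ground truth, and the QuickDASH–accuracy Spearman correlations."""
    metrics_table = load_reported_metrics()
    use_table = load_reported_use_summary()
    demo = load_reported_demographics().sort_values("participant")

    column_averages = {
        side: metrics_table[metrics_table["side"] == side]
        .set_index("participant")[["accuracy", "recall", "specificity", "f1"]]
        .mean()
        .to_dict()
        for side in SIDES
    }
    mean_differences = {
        (method, side): mean_difference(use_table, method, side)
        for method in ("mlm", "counts")
        for side in SIDES
    }
    spearman = {}
    for side in SIDES:
        acc = (
            metrics_table[metrics_table["side"] == side]
            .sort_values("participant")["accuracy"]
            .to_numpy()
        )
        spearman[side] = spearman_tied(demo["quickdash"].to_numpy(), acc)
    return {
        "column_averages": column_averages,
        "mean_differences": mean_differences,
        "spearman_quickdash_accuracy": spearman,
    }
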