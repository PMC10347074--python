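"""Confusion metrics, use summaries, cohort statistics, and the packaged
reported-cohort recomputations."""

import itertools

import numpy as np
import pandas as pd
import pytest

from armuse.errors import ConfigurationError
from armuse.evaluation_stats import (
    ConfusionMatrix,
    confusion,
    load_reported_demographics,
    load_reported_metrics,
    load_reported_use_summary,
    mean_difference,
    metrics,
    recompute_reported_summaries,
    spearman_tied,
    use_summary,
)


def test_confusion_trivial_cases():
    cm = confusion([1, 0, 1], [1, 0, 1])
    assert (cm.tp, cm.tn, cm.fp, cm.fn) == (2, 1, 0, 0)
    cm = confusion([1, 1], [0, 0])
    assert (cm.tp, cm.tn, cm.fp, cm.fn) == (0, 0, 2, 0)


def test_confusion_exhaustive_enumeration_oracle():
    """All 2^4 x 2^4 length-4 label pairs against a literal counter."""
    for pred in itertools.product((0, 1), repeat=4):
        for truth in itertools.product((0, 1), repeat=4):
            cm = confusion(np.array(pred), np.array(truth))
            tp = sum(p == 1 and t == 1 for p, t in zip(pred, truth))
            fp = sum(p == 1 and t == 0 for p, t in zip(pred, truth))
            fn = sum(p == 0 and t == 1 for p, t in zip(pred, truth))
            tn = sum(p == 0 and t == 0 for p, t in zip(pred, truth))
            assert (cm.tp, cm.fp, cm.fn, cm.tn) == (tp, fp, fn, tn)
            assert cm.total == 4


def test_confusion_length_mismatch_rejected():
    with pytest.raises(ConfigurationError):
        confusion([1, 0], [1])


def test_metrics_formula_example():
    rep = metrics(ConfusionMatrix(tp=2, fp=1, fn=1, tn=6))
    assert rep.precision == pytest.approx(2 / 3, abs=1e-15)
    assert rep.recall == pytest.approx(2 / 3, abs=1e-15)
    assert rep.f1 == pytest.approx(2 / 3, abs=1e-15)
    assert rep.accuracy == pytest.approx(0.8, abs=1e-15)
    assert rep.specificity == pytest.approx(6 / 7, abs=1e-15)
    assert not rep.degenerate


def test_metrics_perfect_prediction():
    rep = metrics(ConfusionMatrix(tp=5, fp=0, fn=0, tn=3))
    assert (rep.accuracy, rep.recall, rep.specificity, rep.precision, rep.f1) == (1, 1, 1, 1, 1)


def test_metrics_degenerate_ratios_flagged_not_nan():
    rep = metrics(ConfusionMatrix(tp=0, fp=2, fn=3, tn=5))
    assert rep.recall == 0.0 and rep.precision == 0.0 and rep.f1 == 0.0
    assert "f1" in rep.degenerate
    rep = metrics(ConfusionMatrix(tp=0, fp=0, fn=0, tn=4))
    assert {"recall", "precision", "f1"} <= rep.degenerate
    assert rep.accuracy == 1.0


def test_accuracy_invariant_under_class_swap_but_f1_is_not():
    cm = ConfusionMatrix(tp=8, fp=3, fn=1, tn=20)
    swapped = ConfusionMatrix(tp=cm.tn, fp=cm.fn, fn=cm.fp, tn=cm.tp)
    assert metrics(cm).accuracy == metrics(swapped).accuracy
    assert metrics(cm).f1 != metrics(swapped).f1


def test_metrics_cross_checked_against_sklearn():
    from sklearn.metrics import precision_recall_fscore_support

    rng = np.random.default_rng(12)
    pred, truth = rng.integers(0, 2, 200), rng.integers(0, 2, 200)
    rep = metrics(confusion(pred, truth))
    p, r, f, _ = precision_recall_fscore_support(
        truth, pred, average="binary", zero_division=0
    )
    assert rep.precision == pytest.approx(p, abs=1e-12)
    assert rep.recall == pytest.approx(r, abs=1e-12)
    assert rep.f1 == pytest.approx(f, abs=1e-12)


def test_use_summary_percentages():
    labels_28min = np.ones(int(15.93 * 15), dtype=int)  # 15.93 min of 4-s epochs
    summary = use_summary({"ground_truth": (labels_28min, 4.0)}, 28.45 * 60)
    assert summary.percent["ground_truth"] == pytest.approx(0.56, abs=0.005)
    empty = use_summary({"mlm": (np.zeros(100, dtype=int), 4.0)}, 400.0)
    assert empty.percent["mlm"] == 0.0 and empty.minutes["mlm"] == 0.0
    full = use_summary({"counts": (np.ones(400, dtype=int), 1.0)}, 400.0)
    assert full.percent["counts"] == 1.0
    with pytest.raises(ConfigurationError):
        use_summary({}, 0.0)


def test_mean_difference_basics():
    table = pd.DataFrame(
        {
            "participant": ["A", "A", "B", "B"],
            "side": "left",
            "method": ["ground_truth", "mlm"] * 2,
            "percent": [0.5, 0.6, 0.4, 0.7],
        }
    )
    m, sd = mean_difference(table, "mlm", "left")
    assert m == pytest.approx(0.2) and sd == pytest.approx(np.std([0.1, 0.3], ddof=1))
    m0, sd0 = mean_difference(table, "ground_truth", "left")
    assert m0 == 0.0 and sd0 == 0.0
    with pytest.raises(ConfigurationError):
        mean_difference(table, "counts", "left")


def test_spearman_monotone_and_ties():
    assert spearman_tied([1, 2, 3, 4], [10, 20, 30, 40]).rho == pytest.approx(1.0)
    assert spearman_tied([1, 2, 3, 4], [4, 3, 2, 1]).rho == pytest.approx(-1.0)
    # tie-corrected: Pearson on mid-ranks [1, 2.5, 2.5, 4] vs [1, 2, 3, 4]
    res = spearman_tied([1, 2, 2, 4], [10, 20, 30, 40])
    oracle = np.corrcoef([1, 2.5, 2.5, 4], [1, 2, 3, 4])[0, 1]
    assert res.rho == pytest.approx(oracle, abs=1e-12)
    assert not res.degenerate


def test_spearman_degenerate_and_contract():
    res = spearman_tied([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    assert res.degenerate and np.isnan(res.rho)
    with pytest.raises(ConfigurationError):
        spearman_tied([1, 2], [3, 4])


def test_reported_fixtures_shapes():
    demo = load_reported_demographics()
    assert len(demo) == 10 and demo["participant"].is_unique
    assert demo["quickdash"].between(0, 100).all()
    met = load_reported_metrics()
    assert len(met) == 20 and set(met["side"]) == {"left", "right"}
    use = load_reported_use_summary()
    assert len(use) == 60
    assert use["percent"].between(0, 1).all()
    assert (use["minutes"] >= 0).all()


def test_reported_summary_recomputation_consistency():
    """Recomputing the printed summary rows from the printed per-participant
    values stays within the 2-decimal rounding of the source tables."""
    out = recompute_reported_summaries()
    avg = out["column_averages"]
    assert avg["left"]["accuracy"] == pytest.approx(0.83, abs=0.01)
    assert avg["right"]["recall"] == pytest.approx(0.77, abs=0.01)
    for key, (m, sd) in out["mean_differences"].items():
        assert 0.0 < m < 0.35 and 0.0 < sd < 0.12
    for side, res in out["spearman_quickdash_accuracy"].items():
        assert -1.0 <= res.rho <= 1.0 and not res.degenerate
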