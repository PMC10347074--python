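"""Per-epoch functional/non-functional classifier on the 11-feature vectors.

The original lab-trained model was never published, so this module provides a
retrainable surrogate with the identical feature interface: a random forest by
default (a single decision tree is also offered), trained on min-max-scaled
epoch features and predicting one binary label per 4-s epoch with no temporal
smoothing.  The fitted bundle carries the scaler and a frozen feature-order
signature and refuses to predict on features whose column order differs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.preprocessing import MinMaxScaler
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigurationError, SignatureError
from .feature_extraction import FEATURE_NAMES, apply_minmax, fit_minmax

LEARNER_KINDS = ("random_forest", "decision_tree")

DEFAULT_HYPERPARAMETERS = {
    "random_forest": {"n_estimators": 100, "max_depth": None},
    "decision_tree": {"max_depth": None},
}


@dataclass
class ClassifierModel:
    """A fitted classifier bundled with its scaler and feature signature.

    ``decision_threshold`` is the posterior probability above which an epoch
    is called functional.  The emulated pre-trained model operates
    recall-first — it over-calls functional use at the cost of precision —
    so the pipeline default sits below 0.5; use 0.5 for a neutral argmax
    decision.
    """

    learner_kind: str
    estimator: object
    scaler: MinMaxScaler
    feature_names: tuple[str, ...]
    seed: int
    decision_threshold: float = 0.5
    hyperparameters: dict = field(default_factory=dict)

    def check_signature(self, features: pd.DataFrame) -> None:
        if tuple(features.columns) != self.feature_names:
            raise SignatureError(
                f"feature order mismatch: model expects {self.feature_names}, "
                f"got {tuple(features.columns)}"
            )


def train(
    features: pd.DataFrame,
    labels: np.ndarray,
    learner_kind: str = "random_forest",
    seed: int = 0,
    scaler: MinMaxScaler | None = None,
    class_weight: str | dict | None = None,
    decision_threshold: float = 0.5,
    **hyperparameters,
) -> ClassifierModel:
    """Fit the surrogate classifier.

    ``features`` are *unscaled* epoch features; the scaler is fit here on the
    training corpus (or an already-fitted one can be supplied) and persisted
    with the model.  Deterministic for a fixed seed.
    """
    if learner_kind not in LEARNER_KINDS:
        raise ConfigurationError(f"unknown learner_kind {learner_kind!r}")
    labels = np.asarray(labels)
    if len(features) != labels.shape[0]:
        raise ConfigurationError("features and labels differ in length")
    if np.unique(labels).size < 2:
        raise ConfigurationError("training set contains a single class")

    params = {**DEFAULT_HYPERPARAMETERS[learner_kind], **hyperparameters}
    if scaler is None:
        scaler = fit_minmax(features)
    x = apply_minmax(scaler, features).to_numpy()

    if learner_kind == "random_forest":
        est = RandomForestClassifier(random_state=seed, class_weight=class_weight, **params)
    else:
        est = DecisionTreeClassifier(random_state=seed, class_weight=class_weight, **params)
    est.fit(x, labels)
    if not 0.0 < decision_threshold < 1.0:
        raise ConfigurationError("decision_threshold must lie in (0, 1)")
    return ClassifierModel(
        learner_kind=learner_kind,
        estimator=est,
        scaler=scaler,
        feature_names=tuple(FEATURE_NAMES),
        seed=seed,
        decision_threshold=decision_threshold,
        hyperparameters=params,
    )


def predict_epochs(model: ClassifierModel, features: pd.DataFrame) -> np.ndarray:
    """One binary label (1 functional / 0 non-functional) per epoch; no
    temporal smoothing, so predictions are invariant to epoch order."""
    if len(features) == 0:
        return np.zeros(0, dtype=np.int8)
    model.check_signature(features)
    x = apply_minmax(model.scaler, features).to_numpy()
    classes = list(model.estimator.classes_)
    proba = model.estimator.predict_proba(x)[:, classes.index(1)]
    return (proba >= model.decision_threshold).astype(np.int8)


def predicted_functional_minutes(labels: np.ndarray, epoch_len_s: float = 4.0) -> float:
    """Functional minutes from predicted epoch labels: n_functional × 4 / 60."""
    labels = np.asarray(labels)
    return float(np.sum(labels == 1)) * epoch_len_s / 60.0


def save_model(model: ClassifierModel, path: str | Path) -> None:
    joblib.dump(
        {
            "format": "armuse-classifier-v1",
            "learner_kind": model.learner_kind,
            "estimator": model.estimator,
            "scaler": model.scaler,
            "feature_names": model.feature_names,
            "seed": model.seed,
            "decision_threshold": model.decision_threshold,
            "hyperparameters": model.hyperparameters,
        },
        path,
    )


def load_model(path: str | Path) -> ClassifierModel:
    blob = joblib.load(path)
    if blob.get("format") != "armuse-classifier-v1":
        raise ConfigurationError(f"{path}: not an armuse classifier bundle")
    return ClassifierModel(
        learner_kind=blob["learner_kind"],
        estimator=blob["estimator"],
        scaler=blob["scaler"],
        feature_names=tuple(blob["feature_names"]),
        seed=blob["seed"],
        decision_threshold=blob.get("decision_threshold", 0.5),
        hyperparameters=blob["hyperparameters"],
    )
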