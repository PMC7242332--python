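"""Binary yes/no trial classification with a chance-level gate.

A support vector machine (RBF kernel, library defaults C=1 and
gamma='scale', features z-scored over the training set) is trained on the
feature vectors of a training session and validated by stratified 5-fold
cross-validation.  The model may drive feedback and spelling sessions
only if its cross-validated accuracy exceeds the upper threshold of
chance level — the smallest accuracy k/n whose exact binomial tail
probability under p=0.5 is at most alpha.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import binom
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .signals import FeatureVector
from .synthetic import NO, YES

MIN_PER_CLASS = 5  # below this, 5-fold stratification is impossible


def chance_upper_threshold(n_trials: int, alpha: float = 0.05) -> float:
    """Upper chance-level accuracy threshold by the exact binomial tail.

    Returns the smallest k/n such that P(X >= k | n, p=0.5) <= alpha for
    X ~ Binomial(n, 0.5).  If no k <= n satisfies the bound (tiny n), the
    function returns 1.0; since validation requires accuracy *strictly
    above* the threshold, such a sample size can never pass the gate.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    # sf(k-1) = P(X >= k); scan from the smallest k upward
    for k in range(1, n_trials + 1):
        if binom.sf(k - 1, n_trials, 0.5) <= alpha:
            return k / n_trials
    return 1.0


@dataclass
class TrainedModel:
    """A fitted yes/no classifier with its validation summary.

    ``validated`` is True iff the cross-validated accuracy strictly
    exceeds the chance threshold for the training-set size.
    """

    pipeline: Pipeline
    cv_accuracy: float
    n_training_trials: int
    chance_threshold: float
    feature_mode: str
    channels: tuple[str, ...]
    alpha: float = 0.05

    @property
    def validated(self) -> bool:
        return self.cv_accuracy > self.chance_threshold

    def report(self) -> dict:
        return {
            "cv_accuracy": self.cv_accuracy,
            "n_training_trials": self.n_training_trials,
            "chance_threshold": self.chance_threshold,
            "alpha": self.alpha,
            "validated": self.validated,
            "feature_mode": self.feature_mode,
            "channels": list(self.channels),
        }

    def save_report(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.report(), indent=1))

    def save(self, path: str | Path) -> None:
        """Serialize the fitted model to one file (joblib pickle)."""
        import joblib

        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "TrainedModel":
        import joblib

        return joblib.load(path)


def _as_matrix(features: list[FeatureVector]) -> np.ndarray:
    modes = {f.mode for f in features}
    chans = {f.channels for f in features}
    if len(modes) != 1 or len(chans) != 1:
        raise ValueError("feature vectors mix modes or channel sets")
    return np.vstack([f.values for f in features])


def train_model(features: list[FeatureVector], labels: list[str],
                seed: int = 0, alpha: float = 0.05) -> TrainedModel:
    """Fit the SVM on all trials and cross-validate it (stratified 5-fold).

    Requires both classes present with at least 5 trials each (otherwise
    stratified 5-fold CV is undefined).  The final model is refit on the
    full training set; ``cv_accuracy`` is the mean held-out fold accuracy
    with seeded, shuffled fold assignment.
    """
    if len(features) != len(labels):
        raise ValueError("features and labels differ in length")
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both 'yes' and 'no' trials are required for training")
    if counts.min() < MIN_PER_CLASS:
        raise ValueError(
            f"need at least {MIN_PER_CLASS} trials per class for 5-fold CV, "
            f"got {dict(zip(classes.tolist(), counts.tolist()))}"
        )
    X = _as_matrix(features)
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(kernel="rbf", C=1.0, gamma="scale")),
    ])
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    cv_acc = float(cross_val_score(pipe, X, y, cv=cv, scoring="accuracy").mean())
    pipe.fit(X, y)
    return TrainedModel(
        pipeline=pipe,
        cv_accuracy=cv_acc,
        n_training_trials=len(y),
        chance_threshold=chance_upper_threshold(len(y), alpha),
        feature_mode=features[0].mode,
        channels=features[0].channels,
        alpha=alpha,
    )


def classify_trial(model: TrainedModel, features: FeatureVector) -> str:
    """Predict 'yes' or 'no' for one trial's features (deterministic)."""
    if features.mode != model.feature_mode or features.channels != model.channels:
        raise ValueError(
            "feature mode/channels do not match the model "
            f"({features.mode}/{features.channels} vs "
            f"{model.feature_mode}/{model.channels})"
        )
    label = model.pipeline.predict(features.values.reshape(1, -1))[0]
    return str(label)


def held_out_accuracy(model: TrainedModel, features: list[FeatureVector],
                      labels: list[str]) -> float:
    """Accuracy of the model on an independent trial set."""
    preds = [classify_trial(model, f) for f in features]
    return float(np.mean([p == t for p, t in zip(preds, labels)]))
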