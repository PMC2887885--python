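"""Classifier training and prediction.

Two non-linear classifiers are supported, mirroring the study protocol:

* an RBF-kernel SVM tuned by a coarse-then-refined log-spaced grid search
  over cost and kernel width, scored by 4-fold random cross-validation and
  refit on all training data (one-vs-one multiclass);
* a feed-forward neural network with two hidden layers of 10 units, trained
  by back-propagation with early stopping.

Evaluation follows the chronological half-split: train on the first half of
the recording, test on the second.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import KFold, cross_val_score
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .errors import InvalidInputError, SchemaError
from .features import FeatureMatrix
from .types import REST, DecisionStream, FrameSet

SERIAL_VERSION = 1


@dataclass
class TrainedClassifier:
    """A fitted decision model plus the normalization it was trained under."""

    model_kind: str  # "svm_rbf" | "ann"
    estimator: object
    class_set: tuple[str, ...]
    feature_names: tuple[str, ...]
    normalization_constants: np.ndarray | None
    training_seed: int
    parameters: dict

    def save(self, path: str | Path) -> None:
        payload = {"version": SERIAL_VERSION, "classifier": self}
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @staticmethod
    def load(path: str | Path) -> "TrainedClassifier":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("version") != SERIAL_VERSION:
            raise SchemaError(f"unsupported model file version {payload.get('version')}")
        return payload["classifier"]


def split_half(frames: FrameSet) -> tuple[FrameSet, FrameSet]:
    """Chronological split at the recording-time midpoint.

    Windows whose centers fall before the midpoint form the training half.
    """
    if frames.n_windows < 2:
        raise InvalidInputError("need at least 2 windows to split")
    mid = frames.duration_s / 2.0
    train_mask = frames.window_times < mid
    test_mask = ~train_mask
    if not train_mask.any() or not test_mask.any():
        raise InvalidInputError("midpoint split left one half empty")
    train, test = frames.subset(train_mask), frames.subset(test_mask)
    for name, half in (("train", train), ("test", test)):
        if not np.any(half.window_labels != REST):
            warnings.warn(f"degenerate split: {name} half has no stimulus windows")
    return train, test


def _check_trainable(features: FeatureMatrix) -> tuple[str, ...]:
    classes = tuple(sorted(set(features.window_labels)))
    if len(classes) < 2:
        raise InvalidInputError("training set contains a single class")
    if features.n_windows < 8:
        raise InvalidInputError("need at least 8 training windows")
    return classes


# coarse cost/width grids, decades
_COST_GRID = np.logspace(-1, 3, 5)
_GAMMA_GRID = np.logspace(-3, 1, 5)


def train_svm(
    features: FeatureMatrix, seed: int = 0, cv_folds: int = 4
) -> TrainedClassifier:
    """RBF-SVM with coarse + refined grid search, 4-fold random CV selection."""
    classes = _check_trainable(features)
    X, y = features.values, features.window_labels.astype(str)

    def _cv_score(c: float, g: float) -> float:
        cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        est = SVC(C=c, gamma=g, kernel="rbf", decision_function_shape="ovo")
        return float(np.mean(cross_val_score(est, X, y, cv=cv)))

    def _search(costs: np.ndarray, gammas: np.ndarray) -> tuple[float, float, float]:
        best = (-np.inf, costs[0], gammas[0])
        for c in costs:
            for g in gammas:
                s = _cv_score(c, g)
                if s > best[0]:
                    best = (s, c, g)
        return best

    score, c0, g0 = _search(_COST_GRID, _GAMMA_GRID)
    # refine: 5x5 grid spanning one decade around the coarse optimum
    fine_c = np.logspace(np.log10(c0) - 0.5, np.log10(c0) + 0.5, 5)
    fine_g = np.logspace(np.log10(g0) - 0.5, np.log10(g0) + 0.5, 5)
    fscore, c1, g1 = _search(fine_c, fine_g)
    if fscore < score:
        c1, g1, fscore = c0, g0, score

    est = SVC(C=c1, gamma=g1, kernel="rbf", decision_function_shape="ovo")
    est.fit(X, y)
    return TrainedClassifier(
        model_kind="svm_rbf",
        estimator=est,
        class_set=classes,
        feature_names=features.feature_names,
        normalization_constants=features.normalization_constants,
        training_seed=seed,
        parameters={"C": float(c1), "gamma": float(g1), "cv_accuracy": fscore},
    )


def train_ann(
    features: FeatureMatrix,
    seed: int = 0,
    hidden_layers: int = 2,
    neurons: int = 10,
    max_epochs: int = 500,
) -> TrainedClassifier:
    """Feed-forward network (default 2 hidden layers × 10 units).

    Back-propagation with seeded random initialization, 20% validation
    early stopping (patience 20). One output unit per class present.
    """
    classes = _check_trainable(features)
    X, y = features.values, features.window_labels.astype(str)
    est = MLPClassifier(
        hidden_layer_sizes=(neurons,) * hidden_layers,
        max_iter=max_epochs,
        early_stopping=True,
        validation_fraction=0.2,
        n_iter_no_change=20,
        learning_rate_init=0.01,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, y)
    return TrainedClassifier(
        model_kind="ann",
        estimator=est,
        class_set=classes,
        feature_names=features.feature_names,
        normalization_constants=features.normalization_constants,
        training_seed=seed,
        parameters={"hidden_layer_sizes": (neurons,) * hidden_layers},
    )


def train(features: FeatureMatrix, kind: str = "svm", seed: int = 0, **kw) -> TrainedClassifier:
    if kind in ("svm", "svm_rbf"):
        return train_svm(features, seed=seed, **kw)
    if kind == "ann":
        return train_ann(features, seed=seed, **kw)
    raise InvalidInputError(f"unknown classifier kind {kind!r}")


def predict(model: TrainedClassifier, features: FeatureMatrix) -> DecisionStream:
    """One class decision per window, time-ordered, with ground truth attached."""
    if features.feature_names != model.feature_names:
        raise SchemaError(
            f"feature columns {features.feature_names} do not match the "
            f"model's {model.feature_names}"
        )
    if features.n_windows == 0 or features.values.size == 0:
        return DecisionStream(
            window_times=np.array([]),
            predicted=np.array([], dtype=object),
            truth=np.array([], dtype=object),
        )
    pred = model.estimator.predict(features.values)
    return DecisionStream(
        window_times=features.window_times.copy(),
        predicted=np.asarray(pred, dtype=object),
        truth=features.window_labels.copy(),
    )
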