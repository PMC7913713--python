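"""Margin classifier on 2-s segment features, with temperature-scaled confidences.

The per-segment detector is a support-vector machine; its signed distance
``d`` to the separating hyperplane is converted to a probability by
temperature scaling,

    p_a = 1 / (1 + exp(-a * d)),   a > 0,

and the confidence of a prediction is ``|p_a - 0.5|``.  The classification
threshold sits at ``p_a = 0.5``, i.e. ``d = 0``, for every ``a``, so
temperature scaling can never change the predicted class, and the confidence
ranking is the ranking of ``|d|`` regardless of ``a`` — raw distances are an
admissible confidence score.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, validate_data

__all__ = [
    "SegmentClassifier",
    "train_classifier",
    "temperature_scale",
    "svm_confidence",
    "DEFAULT_A_GRID",
]

#: logarithmic default grid for the temperature parameter a
DEFAULT_A_GRID = tuple(np.logspace(-2, 2, 9))


class SegmentClassifier(ClassifierMixin, BaseEstimator):
    """Patient-independent margin classifier for 2-s segments.

    A standard-scaled SVM (linear kernel and balanced class weights by
    default; the margin direction extrapolates beyond the training manifold
    the way high-dimensional EEG classifiers do, which is what lets
    artifactual segments fool it).
    ``decision_distance`` exposes the signed margin distance ``d``; the
    predicted label is 1 iff ``d > 0``.

    Parameters
    ----------
    kernel, C, gamma, class_weight : forwarded to :class:`sklearn.svm.SVC`.
    regime : "ci" or "fs", records which label regime the model was trained
        under (clear-ictal or full-seizure); informational only.
    """

    def __init__(
        self,
        kernel: str = "linear",
        C: float = 1.0,
        gamma="scale",
        class_weight="balanced",
        regime: str = "ci",
        random_state: int = 0,
    ):
        self.kernel = kernel
        self.C = C
        self.gamma = gamma
        self.class_weight = class_weight
        self.regime = regime
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        classes = np.unique(y)
        if len(classes) != 2 or not set(classes.tolist()) <= {0, 1}:
            raise ValueError("training data must contain both classes {0, 1}")
        self.classes_ = classes
        self.pipeline_ = make_pipeline(
            StandardScaler(),
            SVC(
                kernel=self.kernel,
                C=self.C,
                gamma=self.gamma,
                class_weight=self.class_weight,
                random_state=self.random_state,
            ),
        )
        self.pipeline_.fit(X, y)
        return self

    def decision_distance(self, X) -> np.ndarray:
        """Signed distance d to the separating hyperplane (positive = seizure)."""
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self.pipeline_.decision_function(X)

    def predict(self, X) -> np.ndarray:
        return (self.decision_distance(X) > 0).astype(np.int8)

    def predict_proba(self, X, a: float = 1.0) -> np.ndarray:
        """Temperature-scaled class probabilities at temperature ``a``."""
        p1 = temperature_scale(self.decision_distance(X), a)
        return np.column_stack([1 - p1, p1])


def train_classifier(X, labels, regime: str = "ci", **params) -> SegmentClassifier:
    """Fit a :class:`SegmentClassifier` on pooled cross-patient segments."""
    return SegmentClassifier(regime=regime, **params).fit(X, labels)


def temperature_scale(d, a: float) -> np.ndarray:
    """Map margin distances to probabilities, p_a = 1/(1 + exp(-a d))."""
    if a <= 0:
        raise ValueError("temperature parameter a must be > 0")
    return expit(a * np.asarray(d, dtype=float))


def svm_confidence(p) -> np.ndarray:
    """Confidence of a calibrated prediction, c = |p - 0.5| in [0, 0.5)."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("probabilities must lie strictly in (0, 1)")
    return np.abs(p - 0.5)
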