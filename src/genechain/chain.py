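"""Classifier chain over the 12 binarized label classes, plus baselines.

The chain holds one binary member per indicator column (3 disorder + 9
subclass classes). Member *k* is trained on the input features augmented
with the *true* indicators of all preceding classes in the chain order;
at inference each member consumes the *predicted* indicators of its
predecessors. Decoding takes the argmax of member scores within each
label block, so the output always has exactly one class per block.

A registry maps the eight standard learner names to configured scikit-learn
estimators. 'XGB' is backed by HistGradientBoostingClassifier because the
xgboost package is not available in the runtime environment; it is the
closest in-library gradient-boosted-tree equivalent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import (
    ExtraTreesClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from genechain.errors import ConfigError, DataError
from genechain.preprocess import (
    N_DISORDER,
    N_INDICATOR,
    N_SUBCLASS,
    indicator_to_labels,
    labels_to_indicator,
)

logger = logging.getLogger(__name__)

LEARNER_NAMES = ("LR", "MLP", "DTC", "RFC", "KNN", "ETC", "XGB", "SVC")


def make_learner(name: str, seed: int = 0):
    """Instantiate a registered learner with its fixed hyperparameters.

    ``seed`` overrides any printed ``random_state`` so that every fit in
    the package is reproducible from explicit seeds.
    """
    if name == "ETC":
        return ExtraTreesClassifier(
            n_estimators=300,
            random_state=seed,
            max_depth=300,
            criterion="gini",
            max_features="sqrt",
            bootstrap=False,
            oob_score=False,
            ccp_alpha=0.0,
        )
    if name == "SVC":
        return LinearSVC(
            penalty="l2",
            loss="squared_hinge",
            tol=1e-4,
            C=1.0,
            fit_intercept=True,
            max_iter=1000,
        )
    if name == "LR":
        # penalty='l2' is the default and deprecated as an explicit argument
        return LogisticRegression(
            tol=1e-4,
            C=1.0,
            fit_intercept=True,
            solver="lbfgs",
            max_iter=100,
            random_state=seed,
        )
    if name == "DTC":
        return DecisionTreeClassifier(
            max_depth=300,
            criterion="gini",
            splitter="best",
            ccp_alpha=0.0,
            random_state=seed,
        )
    if name == "RFC":
        return RandomForestClassifier(
            max_depth=300,
            n_estimators=100,
            criterion="gini",
            max_features="sqrt",
            random_state=seed,
            bootstrap=True,
            ccp_alpha=0.0,
        )
    if name == "XGB":
        return HistGradientBoostingClassifier(max_depth=None, random_state=seed)
    if name == "KNN":
        return KNeighborsClassifier(
            n_neighbors=5,
            weights="uniform",
            leaf_size=30,
            metric="minkowski",
            algorithm="auto",
            p=2,
        )
    if name == "MLP":
        return MLPClassifier(
            hidden_layer_sizes=(100,),
            max_iter=300,
            activation="relu",
            solver="adam",
            alpha=0.0001,
            learning_rate="constant",
            tol=1e-4,
            epsilon=1e-8,
            max_fun=15000,
            random_state=seed,
        )
    raise ConfigError(f"unknown learner {name!r}; registered: {LEARNER_NAMES}")


class _ConstantPredictor:
    """Stand-in member for a class that never (or always) occurs in training."""

    def __init__(self, value: int):
        self.value = int(value)

    def fit(self, X, y):  # pragma: no cover - interface symmetry
        return self

    def predict(self, X):
        return np.full(len(X), self.value, dtype=int)

    def score_positive(self, X):
        return np.full(len(X), float(self.value))


def _positive_scores(estimator, X: np.ndarray) -> np.ndarray:
    """Probability-like confidence that the binary label is 1."""
    if isinstance(estimator, _ConstantPredictor):
        return estimator.score_positive(X)
    if hasattr(estimator, "predict_proba"):
        proba = estimator.predict_proba(X)
        classes = list(estimator.classes_)
        if 1 in classes:
            return proba[:, classes.index(1)]
        return np.zeros(len(X))
    # margin-based learners: squash the decision function monotonically
    margin = estimator.decision_function(X)
    return 1.0 / (1.0 + np.exp(-np.clip(margin, -500, 500)))


@dataclass
class ChainPrediction:
    """Raw per-member decisions, scores, and decoded label pairs."""

    raw_indicator: np.ndarray
    scores: np.ndarray
    decoded: np.ndarray


def decode_labels(scores: np.ndarray) -> np.ndarray:
    """Argmax within each label block; ties resolve to the lowest class index.

    Accepts any real-valued (n, 12) score grid and always produces exactly
    one class per block.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != N_INDICATOR:
        raise DataError(f"expected (n, {N_INDICATOR}) scores, got {scores.shape}")
    return np.column_stack(
        [
            scores[:, :N_DISORDER].argmax(axis=1),
            scores[:, N_DISORDER:].argmax(axis=1),
        ]
    )


class ChainModel:
    """Ordered chain of 12 binary classifiers over the indicator columns.

    Parameters
    ----------
    base_learner
        Registered learner name; each member is a fresh instance.
    order
        Permutation of ``range(12)`` giving the chain order. Default is
        identity: disorder classes 0-2 first, then subclass classes.
    seed
        Base seed; member k is seeded with ``seed + k``.
    """

    def __init__(self, base_learner: str = "RFC", order: Sequence[int] | None = None, seed: int = 0):
        if order is None:
            order = list(range(N_INDICATOR))
        order = [int(i) for i in order]
        if sorted(order) != list(range(N_INDICATOR)):
            raise ConfigError(f"order must be a permutation of 0..{N_INDICATOR - 1}")
        self.base_learner = base_learner
        self.order = order
        self.seed = seed
        self.members_: list = []
        self.n_features_in_: int | None = None

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "ChainModel":
        """Fit members sequentially with true-label conditioning."""
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=int)
        if Y.ndim != 2 or Y.shape[1] != N_INDICATOR:
            raise DataError(f"expected (n, {N_INDICATOR}) indicator, got {Y.shape}")
        if set(np.unique(Y)) - {0, 1}:
            raise DataError("indicator matrix must be binary")
        self.n_features_in_ = X.shape[1]
        self.members_ = []
        augmented = X
        for k, cls in enumerate(self.order):
            y = Y[:, cls]
            if y.min() == y.max():
                logger.warning(
                    "class column %d is constant (%d); using a constant member", cls, y[0]
                )
                member = _ConstantPredictor(int(y[0]))
            else:
                member = make_learner(self.base_learner, seed=self.seed + k)
                member.fit(augmented, y)
            self.members_.append(member)
            augmented = np.column_stack([augmented, Y[:, cls]])
        return self

    def predict(self, X: np.ndarray) -> ChainPrediction:
        """Sequential inference: member k sees its predecessors' predictions."""
        if not self.members_:
            raise DataError("chain is not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise DataError(
                f"feature width {X.shape[1]} != training width {self.n_features_in_}"
            )
        n = X.shape[0]
        raw = np.zeros((n, N_INDICATOR), dtype=int)
        scores = np.zeros((n, N_INDICATOR), dtype=float)
        augmented = X
        for k, cls in enumerate(self.order):
            member = self.members_[k]
            if n:
                scores[:, cls] = _positive_scores(member, augmented)
                raw[:, cls] = member.predict(augmented)
            augmented = np.column_stack([augmented, raw[:, cls]]) if n else augmented
        return ChainPrediction(raw, scores, decode_labels(scores))

    def member_input_widths(self) -> list[int]:
        """Width of the feature grid each member was trained on: d, d+1, ..."""
        if self.n_features_in_ is None:
            raise DataError("chain is not fitted")
        return [self.n_features_in_ + k for k in range(len(self.members_))]

    def save(self, path) -> None:
        joblib.dump({"format": 1, "model": self}, path)

    @classmethod
    def load(cls, path) -> "ChainModel":
        payload = joblib.load(path)
        return payload["model"]


class IndependentModel:
    """Control condition: one multiclass learner per label variable, no chaining."""

    def __init__(self, base_learner: str = "RFC", seed: int = 0):
        self.base_learner = base_learner
        self.seed = seed
        self.models_: list = []

    def fit(self, X: np.ndarray, labels: np.ndarray) -> "IndependentModel":
        X = np.asarray(X, dtype=float)
        labels = np.asarray(labels, dtype=int)
        self.models_ = []
        for j in range(2):
            model = make_learner(self.base_learner, seed=self.seed + j)
            model.fit(X, labels[:, j])
            self.models_.append(model)
        return self

    def predict(self, X: np.ndarray) -> ChainPrediction:
        """Predict both labels; scores/raw mirror the chain's contract."""
        if not self.models_:
            raise DataError("model is not fitted")
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        scores = np.zeros((n, N_INDICATOR), dtype=float)
        offsets = (0, N_DISORDER)
        widths = (N_DISORDER, N_SUBCLASS)
        decoded = np.zeros((n, 2), dtype=int)
        for j, model in enumerate(self.models_):
            if n == 0:
                continue
            pred = model.predict(X)
            decoded[:, j] = pred
            if hasattr(model, "predict_proba"):
                proba = model.predict_proba(X)
                for ci, c in enumerate(model.classes_):
                    scores[:, offsets[j] + int(c)] = proba[:, ci]
            elif hasattr(model, "decision_function"):
                margin = model.decision_function(X)
                squash = lambda m: 1.0 / (1.0 + np.exp(-np.clip(m, -500, 500)))
                if margin.ndim == 1:  # two-class margin
                    pos = squash(margin)
                    scores[:, offsets[j] + int(model.classes_[1])] = pos
                    scores[:, offsets[j] + int(model.classes_[0])] = 1.0 - pos
                else:
                    for ci, c in enumerate(model.classes_):
                        scores[:, offsets[j] + int(c)] = squash(margin[:, ci])
            else:  # pragma: no cover
                scores[np.arange(n), offsets[j] + pred] = 1.0
        raw = labels_to_indicator(decoded) if n else np.zeros((0, N_INDICATOR), int)
        return ChainPrediction(raw, scores, decoded)


class CategoricalChain:
    """Two-stage variant: a 3-class disorder model, then a 9-class subclass
    model conditioned on the disorder prediction (one-hot appended)."""

    def __init__(self, base_learner: str = "RFC", seed: int = 0):
        self.base_learner = base_learner
        self.seed = seed
        self.models_: list = []

    def fit(self, X: np.ndarray, labels: np.ndarray) -> "CategoricalChain":
        X = np.asarray(X, dtype=float)
        labels = np.asarray(labels, dtype=int)
        first = make_learner(self.base_learner, seed=self.seed)
        first.fit(X, labels[:, 0])
        onehot = np.eye(N_DISORDER)[labels[:, 0]]
        second = make_learner(self.base_learner, seed=self.seed + 1)
        second.fit(np.column_stack([X, onehot]), labels[:, 1])
        self.models_ = [first, second]
        return self

    def predict(self, X: np.ndarray) -> ChainPrediction:
        if not self.models_:
            raise DataError("model is not fitted")
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if n == 0:
            return ChainPrediction(
                np.zeros((0, N_INDICATOR), int), np.zeros((0, N_INDICATOR)), np.zeros((0, 2), int)
            )
        d = self.models_[0].predict(X)
        onehot = np.eye(N_DISORDER)[d]
        s = self.models_[1].predict(np.column_stack([X, onehot]))
        decoded = np.column_stack([d, s]).astype(int)
        raw = labels_to_indicator(decoded)
        return ChainPrediction(raw, raw.astype(float), decoded)
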