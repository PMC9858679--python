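"""Hybrid class-probability feature stacking from extra-trees + random forest.

Two tree-ensemble base models (ETC, RFC — fixed hyperparameter rows from
the learner registry) are each fitted against both targets, and their
class-probability outputs are concatenated into a 24-wide feature set in
block order [ET-disorder, ET-subclass, RF-disorder, RF-subclass].

Training-row features can be produced either in-sample (each row scored by
models that saw it — the literal construction) or out-of-fold (each row
scored by models fitted with its fold held out — leak-free stacking,
the default). Test rows are always scored by the full models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import joblib
import numpy as np

from genechain.chain import make_learner
from genechain.errors import ConfigError, DataError
from genechain.preprocess import EncodedMatrix, N_DISORDER, N_SUBCLASS
from genechain.schema import DISORDER_CLASSES, SUBCLASS_CLASSES

logger = logging.getLogger(__name__)

BASE_MODELS = ("ETC", "RFC")
TARGET_SIZES = (N_DISORDER, N_SUBCLASS)
TARGET_NAMES = ("disorder", "subclass")
TARGET_CLASS_NAMES = (DISORDER_CLASSES, SUBCLASS_CLASSES)

#: Output width: 2 base models x (3 + 9) classes.
OUTPUT_WIDTH = len(BASE_MODELS) * sum(TARGET_SIZES)


@dataclass(frozen=True)
class ETRFConfig:
    """Configuration for the hybrid feature constructor."""

    mode: str = "out_of_fold"
    n_folds: int = 5
    append_raw: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("out_of_fold", "in_sample"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "out_of_fold" and self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")


def _as_array(X) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(X, EncodedMatrix):
        return np.asarray(X.values, dtype=float), list(X.feature_names)
    return np.asarray(X, dtype=float), None


def _aligned_proba(model, X: np.ndarray, n_classes: int) -> np.ndarray:
    """predict_proba with columns placed at the global class codes."""
    out = np.zeros((X.shape[0], n_classes), dtype=float)
    proba = model.predict_proba(X)
    for ci, c in enumerate(model.classes_):
        out[:, int(c)] = proba[:, ci]
    return out


class ETRFTransformer:
    """Fitted hybrid-feature constructor.

    Attributes after :meth:`fit`:

    - ``full_models_``: {(base, target_index): fitted estimator} on all rows.
    - ``fold_assignments_``: per-training-row fold id (out_of_fold mode).
    - ``fold_models_``: {(base, target_index, fold): estimator fitted with
      that fold held out} — kept so leak-freedom is independently checkable.
    - ``oof_features_``: cached training-row feature grid.
    """

    def __init__(self, config: ETRFConfig = ETRFConfig()):
        self.config = config
        self.full_models_: dict = {}
        self.fold_models_: dict = {}
        self.fold_assignments_: np.ndarray | None = None
        self.oof_features_: np.ndarray | None = None
        self.feature_names_: list[str] | None = None
        self.n_train_: int | None = None
        self.n_features_in_: int | None = None

    # -- fitting -----------------------------------------------------------

    def fit(self, X, labels: np.ndarray) -> "ETRFTransformer":
        """Fit the four (base model x target) learners.

        ``labels`` is the (n, 2) integer label-pair grid. Every disorder
        and subclass code must occur at least once.
        """
        values, names = _as_array(X)
        labels = np.asarray(labels, dtype=int)
        if values.shape[0] != labels.shape[0]:
            raise DataError("X and labels disagree on row count")
        for t, (size, class_names) in enumerate(zip(TARGET_SIZES, TARGET_CLASS_NAMES)):
            present = set(np.unique(labels[:, t]))
            missing = [class_names[c] for c in range(size) if c not in present]
            if missing:
                raise DataError(
                    f"target class(es) absent from the training set: {missing}"
                )

        self.feature_names_ = names
        self.n_train_ = values.shape[0]
        self.n_features_in_ = values.shape[1]
        n = values.shape[0]

        for b, base in enumerate(BASE_MODELS):
            for t in range(2):
                model = make_learner(base, seed=self.config.seed + 10 * b + t)
                model.fit(values, labels[:, t])
                self.full_models_[(base, t)] = model

        if self.config.mode == "out_of_fold":
            rng = np.random.default_rng(self.config.seed)
            folds = np.tile(np.arange(self.config.n_folds), n // self.config.n_folds + 1)[:n]
            rng.shuffle(folds)
            self.fold_assignments_ = folds
            oof = np.zeros((n, OUTPUT_WIDTH), dtype=float)
            for fold in range(self.config.n_folds):
                holdout = folds == fold
                fit_rows = ~holdout
                col = 0
                for b, base in enumerate(BASE_MODELS):
                    for t, size in enumerate(TARGET_SIZES):
                        model = make_learner(
                            base, seed=self.config.seed + 100 * (fold + 1) + 10 * b + t
                        )
                        model.fit(values[fit_rows], labels[fit_rows, t])
                        self.fold_models_[(base, t, fold)] = model
                        oof[holdout, col : col + size] = _aligned_proba(
                            model, values[holdout], size
                        )
                        col += size
            self.oof_features_ = oof
        else:
            self.oof_features_ = self._full_model_features(values)
        return self

    # -- transforming ------------------------------------------------------

    def _full_model_features(self, values: np.ndarray) -> np.ndarray:
        blocks = []
        for base in BASE_MODELS:
            for t, size in enumerate(TARGET_SIZES):
                blocks.append(_aligned_proba(self.full_models_[(base, t)], values, size))
        return np.hstack(blocks)

    def transform(self, X, is_training_set: bool = False) -> np.ndarray:
        """Produce the hybrid feature grid for X.

        Training rows (``is_training_set=True``) get the cached fit-time
        features — out-of-fold probabilities in the default mode. Test rows
        always get full-model probabilities.
        """
        if not self.full_models_:
            raise DataError("transformer is not fitted")
        values, names = _as_array(X)
        if self.feature_names_ is not None and names is not None and names != self.feature_names_:
            raise DataError("feature names differ from those seen at fit time")
        if is_training_set:
            if values.shape[0] != self.n_train_:
                raise DataError(
                    f"training-set transform expects the {self.n_train_} fit rows, "
                    f"got {values.shape[0]}"
                )
            features = self.oof_features_.copy()
        else:
            features = self._full_model_features(values)
        if self.config.append_raw:
            features = np.hstack([features, values])
        return features

    def describe_blocks(self) -> list[tuple[str, str, str]]:
        """Ordered (base model, target, class-name) descriptor per output column."""
        if not self.full_models_:
            raise DataError("transformer is not fitted")
        layout = []
        for base in BASE_MODELS:
            label = "extra-trees" if base == "ETC" else "random-forest"
            for t in range(2):
                for cls in TARGET_CLASS_NAMES[t]:
                    layout.append((label, TARGET_NAMES[t], cls))
        if self.config.append_raw:
            names = self.feature_names_ or [f"x{i}" for i in range(self.n_features_in_)]
            layout.extend(("raw", "feature", name) for name in names)
        return layout

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        joblib.dump({"format": 1, "transformer": self}, path)

    @classmethod
    def load(cls, path) -> "ETRFTransformer":
        payload = joblib.load(path)
        return payload["transformer"]
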