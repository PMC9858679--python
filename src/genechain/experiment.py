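"""Seeded experiment grids: learners × splits × feature modes × balance modes.

Each arm runs the full pipeline — load/generate → drop → encode →
(balance) → split → (fit hybrid features) → fit model → predict →
evaluate — with every stochastic step seeded from the master seed via a
stable hash, so arms are individually reproducible and the combined grid
CSV is identical across reruns.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from genechain.chain import CategoricalChain, ChainModel, IndependentModel, LEARNER_NAMES
from genechain.errors import ConfigError, DataError
from genechain.etrf import ETRFConfig, ETRFTransformer
from genechain.metrics import EvaluationReport, evaluate_predictions, reports_to_frame
from genechain.preprocess import (
    SplitSpec,
    balance_undersample,
    labels_to_indicator,
    prepare_dataset,
    train_test_split,
)
from genechain.schema import PatientTable, read_patient_csv
from genechain.synthetic import SyntheticConfig, generate

logger = logging.getLogger(__name__)

FEATURE_MODES = ("raw", "etrf")
BALANCE_MODES = ("imbalanced", "balanced")
ARCHITECTURES = ("auto", "chain", "independent", "categorical_chain")


@dataclass(frozen=True)
class ExperimentConfig:
    """Grid definition.

    ``data`` is a CSV path (str) or a :class:`SyntheticConfig`.
    ``architecture='auto'`` uses independent per-label models on raw
    features and the classifier chain on hybrid features, mirroring the
    with/without-technique arms of the replica grid.
    """

    data: object
    learners: tuple[str, ...] = ("RFC",)
    split_fractions: tuple[float, ...] = (0.8,)
    feature_modes: tuple[str, ...] = ("raw", "etrf")
    balance_modes: tuple[str, ...] = ("imbalanced",)
    architecture: str = "auto"
    etrf_mode: str = "out_of_fold"
    stratified_split: bool = True
    balance_before_split: bool = True
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.learners or not self.split_fractions:
            raise ConfigError("learners and split_fractions must be non-empty")
        bad = [m for m in self.learners if m not in LEARNER_NAMES]
        if bad:
            raise ConfigError(f"unregistered learner(s): {bad}")
        if any(m not in FEATURE_MODES for m in self.feature_modes):
            raise ConfigError(f"feature_modes must be drawn from {FEATURE_MODES}")
        if any(m not in BALANCE_MODES for m in self.balance_modes):
            raise ConfigError(f"balance_modes must be drawn from {BALANCE_MODES}")
        if self.architecture not in ARCHITECTURES:
            raise ConfigError(f"architecture must be one of {ARCHITECTURES}")


def derive_seed(master_seed: int, *parts) -> int:
    """Stable 32-bit seed from the master seed and arm coordinates."""
    key = "|".join([str(master_seed), *map(str, parts)])
    return int(hashlib.sha256(key.encode()).hexdigest()[:8], 16)


@dataclass
class ArmRecord:
    """Run-ledger entry for one arm."""

    learner: str
    split_fraction: float
    feature_mode: str
    balance_mode: str
    seed: int
    status: str = "ok"
    error: str = ""
    elapsed_seconds: float = 0.0


def _load_table(data) -> PatientTable:
    if isinstance(data, PatientTable):
        return data
    if isinstance(data, SyntheticConfig):
        table, _ = generate(data)
        return table
    return read_patient_csv(data)


def run_arm(
    X: np.ndarray,
    labels: np.ndarray,
    learner: str,
    split_fraction: float,
    feature_mode: str,
    balance_mode: str,
    config: ExperimentConfig,
    seed: int,
) -> EvaluationReport:
    """Execute one arm on an already-encoded dataset."""
    if balance_mode == "balanced" and config.balance_before_split:
        X, labels = balance_undersample(X, labels, seed=seed)

    X_tr, y_tr, X_te, y_te = train_test_split(
        X, labels, SplitSpec(split_fraction, seed=seed, stratified=config.stratified_split)
    )
    if balance_mode == "balanced" and not config.balance_before_split:
        X_tr, y_tr = balance_undersample(X_tr, y_tr, seed=seed)

    t0 = time.perf_counter()
    if feature_mode == "etrf":
        transformer = ETRFTransformer(ETRFConfig(mode=config.etrf_mode, seed=seed))
        transformer.fit(X_tr, y_tr)
        F_tr = transformer.transform(X_tr, is_training_set=True)
        F_te = transformer.transform(X_te, is_training_set=False)
    else:
        F_tr, F_te = X_tr, X_te

    architecture = config.architecture
    if architecture == "auto":
        architecture = "independent" if feature_mode == "raw" else "chain"

    if architecture == "chain":
        model = ChainModel(base_learner=learner, seed=seed)
        model.fit(F_tr, labels_to_indicator(y_tr))
    elif architecture == "categorical_chain":
        model = CategoricalChain(base_learner=learner, seed=seed)
        model.fit(F_tr, y_tr)
    else:
        model = IndependentModel(base_learner=learner, seed=seed)
        model.fit(F_tr, y_tr)
    elapsed = time.perf_counter() - t0

    pred = model.predict(F_te)
    return evaluate_predictions(
        indicator_true=labels_to_indicator(y_te),
        indicator_pred=labels_to_indicator(pred.decoded),
        labels_true=y_te,
        labels_pred=pred.decoded,
        training_time_seconds=elapsed,
        arm={
            "learner": learner,
            "split_fraction": split_fraction,
            "feature_mode": feature_mode,
            "balance_mode": balance_mode,
            "seed": seed,
        },
    )


def run_experiment(
    config: ExperimentConfig,
) -> tuple[list[ArmRecord], list[EvaluationReport], pd.DataFrame]:
    """Run the full grid; a failing arm is logged and the grid continues.

    Returns (ledger, reports, combined tidy frame).
    """
    table = _load_table(config.data)
    X, targets = prepare_dataset(table)
    ledger: list[ArmRecord] = []
    reports: list[EvaluationReport] = []

    for learner in config.learners:
        for frac in config.split_fractions:
            for fmode in config.feature_modes:
                for bmode in config.balance_modes:
                    seed = derive_seed(config.master_seed, learner, frac, fmode, bmode)
                    record = ArmRecord(learner, frac, fmode, bmode, seed)
                    start = time.perf_counter()
                    try:
                        report = run_arm(
                            X.values,
                            targets.labels,
                            learner,
                            frac,
                            fmode,
                            bmode,
                            config,
                            seed,
                        )
                        reports.append(report)
                    except Exception as exc:  # arm isolation
                        logger.error(
                            "arm (%s, %s, %s, %s) failed: %s", learner, frac, fmode, bmode, exc
                        )
                        record.status = "error"
                        record.error = str(exc)
                    record.elapsed_seconds = time.perf_counter() - start
                    ledger.append(record)

    combined = reports_to_frame(reports) if reports else pd.DataFrame()
    return ledger, reports, combined


def compare_modes(combined: pd.DataFrame) -> pd.DataFrame:
    """Paired raw-vs-etrf metric deltas per (learner, split, balance mode).

    Positive deltas mean the hybrid-feature arm scored higher. Unpaired
    arms are skipped with a warning.
    """
    keys = ["learner", "split_fraction", "balance_mode"]
    metrics = [
        "macro_accuracy_pct",
        "macro_accuracy_example_based_pct",
        "hamming_loss",
        "alpha_evaluation_score_pct",
    ]
    rows = []
    for key, group in combined.groupby(keys):
        modes = set(group["feature_mode"])
        if {"raw", "etrf"} - modes:
            logger.warning("unpaired arm %s (modes present: %s); skipped", key, modes)
            continue
        raw = group[group["feature_mode"] == "raw"].iloc[0]
        etrf = group[group["feature_mode"] == "etrf"].iloc[0]
        row = dict(zip(keys, key))
        for m in metrics:
            row[f"delta_{m}"] = float(etrf[m] - raw[m])
        rows.append(row)
    return pd.DataFrame(rows)
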