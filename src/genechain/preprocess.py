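"""Feature dropping, categorical encoding, target encoding, balancing, splitting.

The encoder implements the fixed integer code maps (alphabet {-1, 0, 1, 2}),
fills remaining nulls with zero, and is total and deterministic. The drop
list is fixed: thirteen identifier/low-importance columns go, 'Test 4' stays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from genechain import schema
from genechain.errors import DataError, EncodingError
from genechain.schema import (
    DISORDER_CLASSES,
    SUBCLASS_CLASSES,
    TARGET_COLUMNS,
    TARGET_DISORDER,
    TARGET_SUBCLASS,
    PatientTable,
    column_spec,
)

logger = logging.getLogger(__name__)

#: Columns removed before modelling ('Test 4' is deliberately retained).
DROP_COLUMNS: tuple[str, ...] = (
    "Patient Id",
    "Patient First Name",
    "Family Name",
    "Father's name",
    "Institute Name",
    "Location of Institute",
    "Place of birth",
    "Parental consent",
    "Test 1",
    "Test 2",
    "Test 3",
    "Test 5",
    "Autopsy shows birth defect (if applicable)",
)

#: Binary Yes/No -> 1/0 columns.
_YES_NO_COLUMNS = (
    "Genes in mother's side",
    "Inherited from father",
    "Maternal gene",
    "Paternal gene",
    "Assisted conception IVF/ART",
    "History of anomalies in previous pregnancies",
    "Folic acid details (peri-conceptional)",
    "H/O serious maternal illness",
)

#: category-string -> integer code, per feature column. Keys are canonical
#: category strings from the schema registry; lookups are case-insensitive.
ENCODING_MAPS: dict[str, dict[str, int]] = {
    **{col: {"Yes": 1, "No": 0} for col in _YES_NO_COLUMNS},
    "H/O radiation exposure (X-ray)": {"Yes": 1, "No": 0, "Not applicable": -1},
    "H/O substance abuse": {"Yes": 1, "No": 0, "Not applicable": -1},
    "Status": {"Deceased": 0, "Alive": 1},
    "Respiratory Rate (breaths/min)": {"Normal (30-60)": 0, "Tachypnea": 1},
    "Heart Rate (rates/min": {"Normal": 0, "Tachypnea": 1},
    "Follow-up": {"Low": 0, "High": 1},
    "Gender": {"Male": 0, "Female": 1, "Ambiguous": 2},
    "Birth asphyxia": {"No record": 0, "Not available": 0, "No": 0, "Yes": 1},
    "Birth defects": {"Singular": 0, "Multiple": 1},
    "Blood test result": {"normal": 0, "abnormal": 1},
}

CODE_ALPHABET = frozenset({-1, 0, 1, 2})
assert all(set(m.values()) <= CODE_ALPHABET for m in ENCODING_MAPS.values())


def encoding_maps_to_text() -> str:
    """Serialize the encoding maps as auditable ``column::category=code`` lines."""
    lines = []
    for col in sorted(ENCODING_MAPS):
        for cat, code in ENCODING_MAPS[col].items():
            lines.append(f"{col}::{cat}={code}")
    return "\n".join(lines) + "\n"


def encoding_maps_from_text(text: str) -> dict[str, dict[str, int]]:
    """Parse the key-value export format produced by :func:`encoding_maps_to_text`."""
    maps: dict[str, dict[str, int]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        head, _, code = line.rpartition("=")
        col, _, cat = head.partition("::")
        maps.setdefault(col, {})[cat] = int(code)
    return maps


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------


def drop_noncontributing(table: PatientTable) -> PatientTable:
    """Remove the fixed list of identifier / low-importance columns.

    Idempotent; already-absent columns are skipped with a warning.
    """
    optional = {c.name for c in schema.OPTIONAL_COLUMNS}
    present = [c for c in DROP_COLUMNS if c in table.df.columns]
    absent = [c for c in DROP_COLUMNS if c not in table.df.columns and c not in optional]
    if absent:
        logger.warning("drop list columns already absent: %s", absent)
    return PatientTable(table.df.drop(columns=present))


@dataclass
class EncodedMatrix:
    """Fully numeric feature matrix with provenance."""

    values: np.ndarray
    feature_names: list[str]
    provenance: dict = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.feature_names)


def encode_features(table: PatientTable) -> EncodedMatrix:
    """Encode all feature columns to a numeric matrix, nulls filled with 0.

    Expects :func:`drop_noncontributing` to have been applied; any feature
    column still present is encoded. Unseen category strings raise
    :class:`EncodingError` naming the column and value.
    """
    cols = [
        c
        for c in table.df.columns
        if c not in TARGET_COLUMNS and column_spec(c).role == "feature"
    ]
    out = np.zeros((table.n_rows, len(cols)), dtype=float)
    for k, col in enumerate(cols):
        spec = column_spec(col)
        series = table.df[col]
        if spec.value_kind == "numeric":
            vals = series.to_numpy(dtype=float)
        else:
            mapping = ENCODING_MAPS.get(col)
            if mapping is None:
                raise EncodingError(col, "<no registered encoding map>")
            lut = {cat.strip().lower(): code for cat, code in mapping.items()}
            vals = np.zeros(len(series), dtype=float)
            for i, v in enumerate(series):
                if pd.isna(v):
                    vals[i] = np.nan
                else:
                    key = str(v).strip().lower()
                    if key not in lut:
                        raise EncodingError(col, v)
                    vals[i] = lut[key]
        out[:, k] = np.nan_to_num(vals, nan=0.0)
    return EncodedMatrix(
        out,
        cols,
        provenance={"dropped": list(DROP_COLUMNS), "encoding_maps": dict(ENCODING_MAPS)},
    )


N_DISORDER = len(DISORDER_CLASSES)
N_SUBCLASS = len(SUBCLASS_CLASSES)
N_INDICATOR = N_DISORDER + N_SUBCLASS  # 12


@dataclass
class TargetEncoding:
    """Integer-coded label pairs plus their one-hot-per-block indicator form.

    ``labels[:, 0]`` holds disorder codes 0..2, ``labels[:, 1]`` subclass
    codes 0..8; ``indicator`` is the (n, 12) concatenated one-hot form.
    ``kept_index`` maps encoded rows back to input-table row positions.
    """

    labels: np.ndarray
    indicator: np.ndarray
    kept_index: np.ndarray
    n_excluded: int


def labels_to_indicator(labels: np.ndarray) -> np.ndarray:
    """(n, 2) integer label pairs -> (n, 12) indicator matrix."""
    labels = np.asarray(labels, dtype=int)
    n = labels.shape[0]
    ind = np.zeros((n, N_INDICATOR), dtype=int)
    ind[np.arange(n), labels[:, 0]] = 1
    ind[np.arange(n), N_DISORDER + labels[:, 1]] = 1
    return ind


def indicator_to_labels(indicator: np.ndarray) -> np.ndarray:
    """Inverse of :func:`labels_to_indicator` for valid one-hot blocks."""
    indicator = np.asarray(indicator)
    return np.column_stack(
        [
            indicator[:, :N_DISORDER].argmax(axis=1),
            indicator[:, N_DISORDER:].argmax(axis=1),
        ]
    )


def encode_targets(table: PatientTable) -> TargetEncoding:
    """Encode the two targets to integer codes and indicator form.

    Rows with a null in either target are excluded; the exclusion count is
    reported in the result.
    """
    disorder_lut = {c.strip().lower(): i for i, c in enumerate(DISORDER_CLASSES)}
    subclass_lut = {c.strip().lower(): i for i, c in enumerate(SUBCLASS_CLASSES)}

    dis = table.df[TARGET_DISORDER]
    sub = table.df[TARGET_SUBCLASS]
    keep = dis.notna().to_numpy() & sub.notna().to_numpy()
    kept_index = np.flatnonzero(keep)

    labels = np.zeros((len(kept_index), 2), dtype=int)
    for out_i, row_i in enumerate(kept_index):
        d = str(dis.iloc[row_i]).strip().lower()
        s = str(sub.iloc[row_i]).strip().lower()
        if d not in disorder_lut:
            raise EncodingError(TARGET_DISORDER, dis.iloc[row_i])
        if s not in subclass_lut:
            raise EncodingError(TARGET_SUBCLASS, sub.iloc[row_i])
        labels[out_i] = (disorder_lut[d], subclass_lut[s])

    return TargetEncoding(
        labels=labels,
        indicator=labels_to_indicator(labels) if len(labels) else np.zeros((0, N_INDICATOR), int),
        kept_index=kept_index,
        n_excluded=int(table.n_rows - len(kept_index)),
    )


def prepare_dataset(table: PatientTable) -> tuple[EncodedMatrix, TargetEncoding]:
    """Full front half of the pipeline: drop, exclude null-label rows, encode."""
    dropped = drop_noncontributing(table)
    targets = encode_targets(dropped)
    kept = PatientTable(dropped.df.iloc[targets.kept_index])
    X = encode_features(kept)
    return X, targets


def balance_undersample(
    X: np.ndarray | EncodedMatrix,
    labels: np.ndarray,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Undersample so each disorder class keeps exactly the minimum class count.

    Rows are sampled uniformly without replacement per class; original row
    order is preserved in the output. The subclass distribution is whatever
    survives — only the disorder label is balanced.
    """
    values = X.values if isinstance(X, EncodedMatrix) else np.asarray(X)
    labels = np.asarray(labels)
    if values.shape[0] != labels.shape[0]:
        raise DataError("X and labels disagree on row count")
    disorder = labels[:, 0]
    counts = np.bincount(disorder, minlength=N_DISORDER)
    if (counts == 0).any():
        empty = [DISORDER_CLASSES[i] for i in np.flatnonzero(counts == 0)]
        raise DataError(f"disorder class(es) with zero samples: {empty}")
    m = int(counts.min())
    rng = np.random.default_rng(seed)
    chosen = []
    for k in range(N_DISORDER):
        idx = np.flatnonzero(disorder == k)
        chosen.append(rng.choice(idx, size=m, replace=False))
    sel = np.sort(np.concatenate(chosen))
    return values[sel], labels[sel]


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split request.

    ``train_fraction`` is free-form; the grid replicas use
    {0.70, 0.80, 0.85, 0.90}.
    """

    train_fraction: float
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise DataError(f"train_fraction must lie in (0,1): {self.train_fraction}")


def train_test_split(
    X: np.ndarray | EncodedMatrix,
    labels: np.ndarray,
    spec: SplitSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive, seeded train/test partition.

    When stratified, each joint (disorder, subclass) stratum contributes
    ``round(train_fraction * n_stratum)`` training rows (±1 by rounding);
    singleton strata fall back to a global coin flip with a warning.

    Returns ``(X_train, y_train, X_test, y_test)``.
    """
    values = X.values if isinstance(X, EncodedMatrix) else np.asarray(X)
    labels = np.asarray(labels)
    n = values.shape[0]
    if n < 2:
        raise DataError("need at least 2 rows to split")
    rng = np.random.default_rng(spec.seed)

    train_mask = np.zeros(n, dtype=bool)
    if spec.stratified:
        joint = labels[:, 0] * 100 + labels[:, 1]
        for key in np.unique(joint):
            idx = np.flatnonzero(joint == key)
            if len(idx) == 1:
                logger.warning(
                    "stratum %s has a single sample; assigning by global fraction", key
                )
                train_mask[idx[0]] = rng.random() < spec.train_fraction
                continue
            k = int(round(spec.train_fraction * len(idx)))
            k = min(max(k, 1), len(idx) - 1)  # keep both sides non-empty per stratum
            perm = rng.permutation(idx)
            train_mask[perm[:k]] = True
    else:
        k = int(round(spec.train_fraction * n))
        k = min(max(k, 1), n - 1)
        perm = rng.permutation(n)
        train_mask[perm[:k]] = True

    return (
        values[train_mask],
        labels[train_mask],
        values[~train_mask],
        labels[~train_mask],
    )
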