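"""Patient-table schema registry and CSV I/O.

The registry holds the 44 columns of the genomes-dataset layout (exact
header strings, including the unbalanced parenthesis in
``'Heart Rate (rates/min'``), plus one *optional* identifier column,
``'Parental consent'``, which some distributions of the dataset carry.
Every other module derives column names from this registry; none
re-declares them.

CSV dialect: comma-separated, UTF-8, mandatory header row, empty string
means null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from genechain.errors import CellError, SchemaError

logger = logging.getLogger(__name__)

# --------------------------------------------------------------------------
# class alphabets
# --------------------------------------------------------------------------

#: Disorder classes in integer-code order (code 0, 1, 2).
DISORDER_CLASSES: tuple[str, ...] = (
    "Mitochondrial genetic inheritance disorders",
    "Multifactorial genetic inheritance disorders",
    "Single-gene inheritance diseases",
)

#: Subclass classes in integer-code order (codes 0..8).
SUBCLASS_CLASSES: tuple[str, ...] = (
    "Leber's hereditary optic neuropathy",
    "Diabetes",
    "Leigh syndrome",
    "Cancer",
    "Cystic fibrosis",
    "Tay-Sachs",
    "Hemochromatosis",
    "Mitochondrial myopathy",
    "Alzheimer's",
)

TARGET_DISORDER = "Genetic Disorder"
TARGET_SUBCLASS = "Disorder Subclass"
TARGET_COLUMNS: tuple[str, str] = (TARGET_DISORDER, TARGET_SUBCLASS)

YES_NO = ("Yes", "No")
YES_NO_NA = ("Yes", "No", "Not applicable")

# --------------------------------------------------------------------------
# column registry
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ColumnSpec:
    """One column of the patient table.

    Parameters
    ----------
    name
        Exact header string.
    role
        ``'identifier'`` (dropped before modelling), ``'feature'`` or
        ``'target'``.
    value_kind
        ``'numeric'``, ``'categorical'`` or ``'free_text'``.
    allowed_values
        Category alphabet for categorical columns (matched
        case-insensitively on read).
    nullable
        Whether nulls are legal.
    observed_count
        Non-null count out of 31,548 rows in the reference distribution;
        used to derive a realistic per-column missingness profile.
    """

    name: str
    role: str
    value_kind: str
    allowed_values: tuple[str, ...] | None = None
    nullable: bool = True
    observed_count: int = 31_548


def _c(name, role, kind, allowed=None, count=31_548) -> ColumnSpec:
    return ColumnSpec(name, role, kind, allowed, True, count)


#: The 44 registered columns, in canonical order.
COLUMN_REGISTRY: tuple[ColumnSpec, ...] = (
    _c("Patient Id", "identifier", "free_text", None, 31_548),
    _c("Patient Age", "feature", "numeric", None, 30_121),
    _c("Genes in mother's side", "feature", "categorical", YES_NO, 31_548),
    _c("Inherited from father", "feature", "categorical", YES_NO, 30_691),
    _c("Maternal gene", "feature", "categorical", YES_NO, 25_015),
    _c("Paternal gene", "feature", "categorical", YES_NO, 31_548),
    _c("Blood cell count (mcL)", "feature", "numeric", None, 31_548),
    _c("Patient First Name", "identifier", "free_text", None, 31_548),
    _c("Family Name", "identifier", "free_text", None, 12_540),
    _c("Father's name", "identifier", "free_text", None, 31_548),
    _c("Mother's age", "feature", "numeric", None, 25_512),
    _c("Father's age", "feature", "numeric", None, 25_562),
    _c("Institute Name", "identifier", "free_text", None, 24_406),
    _c("Location of Institute", "identifier", "free_text", None, 31_548),
    _c("Status", "feature", "categorical", ("Deceased", "Alive"), 31_548),
    _c(
        "Respiratory Rate (breaths/min)",
        "feature",
        "categorical",
        ("Normal (30-60)", "Tachypnea"),
        26_513,
    ),
    # header printed with an unbalanced parenthesis; preserved verbatim
    _c("Heart Rate (rates/min", "feature", "categorical", ("Normal", "Tachypnea"), 26_535),
    _c("Test 1", "feature", "numeric", None, 29_421),
    _c("Test 2", "feature", "numeric", None, 29_396),
    _c("Test 3", "feature", "numeric", None, 29_401),
    _c("Test 4", "feature", "numeric", None, 29_408),
    _c("Test 5", "feature", "numeric", None, 29_378),
    _c("Follow-up", "feature", "categorical", ("Low", "High"), 29_382),
    _c("Gender", "feature", "categorical", ("Male", "Female", "Ambiguous"), 29_375),
    _c(
        "Birth asphyxia",
        "feature",
        "categorical",
        ("No record", "Not available", "No", "Yes"),
        29_409,
    ),
    _c(
        "Autopsy shows birth defect (if applicable)",
        "feature",
        "categorical",
        ("None", "Not applicable", "No", "Yes"),
        30_522,
    ),
    _c("Place of birth", "identifier", "free_text", None, 29_424),
    _c("Folic acid details (peri-conceptional)", "feature", "categorical", YES_NO, 29_431),
    _c("H/O serious maternal illness", "feature", "categorical", YES_NO, 29_396),
    _c("H/O radiation exposure (X-ray)", "feature", "categorical", YES_NO_NA, 29_395),
    _c("H/O substance abuse", "feature", "categorical", YES_NO_NA, 29_353),
    _c("Assisted conception IVF/ART", "feature", "categorical", YES_NO, 29_426),
    _c(
        "History of anomalies in previous pregnancies",
        "feature",
        "categorical",
        YES_NO,
        29_376,
    ),
    _c("No. of previous abortion", "feature", "numeric", None, 29_386),
    _c("Birth defects", "feature", "categorical", ("Singular", "Multiple"), 29_394),
    _c(
        "White Blood cell count (thousand per microliter)",
        "feature",
        "numeric",
        None,
        29_400,
    ),
    _c("Blood test result", "feature", "categorical", ("normal", "abnormal"), 29_403),
    _c("Symptom 1", "feature", "numeric", None, 29_393),
    _c("Symptom 2", "feature", "numeric", None, 29_326),
    _c("Symptom 3", "feature", "numeric", None, 29_447),
    _c("Symptom 4", "feature", "numeric", None, 29_435),
    _c("Symptom 5", "feature", "numeric", None, 29_395),
    _c(TARGET_DISORDER, "target", "categorical", DISORDER_CLASSES, 19_937),
    _c(TARGET_SUBCLASS, "target", "categorical", SUBCLASS_CLASSES, 19_915),
)

#: Known columns that are legal but not required (role=identifier).
OPTIONAL_COLUMNS: tuple[ColumnSpec, ...] = (
    _c("Parental consent", "identifier", "free_text", None, 31_548),
)

REFERENCE_N_ROWS = 31_548

COLUMN_NAMES: tuple[str, ...] = tuple(c.name for c in COLUMN_REGISTRY)
_ALL_SPECS: dict[str, ColumnSpec] = {c.name: c for c in COLUMN_REGISTRY + OPTIONAL_COLUMNS}

assert len(COLUMN_REGISTRY) == 44
assert sum(1 for c in COLUMN_REGISTRY if c.role == "target") == 2


def column_spec(name: str) -> ColumnSpec:
    """Look up a registered (or optional) column by exact name."""
    try:
        return _ALL_SPECS[name]
    except KeyError:
        raise SchemaError(f"unknown column {name!r}") from None


def feature_columns() -> list[str]:
    """Names of role=feature columns, registry order."""
    return [c.name for c in COLUMN_REGISTRY if c.role == "feature"]


def identifier_columns() -> list[str]:
    """Names of role=identifier columns, including optional ones."""
    return [c.name for c in COLUMN_REGISTRY + OPTIONAL_COLUMNS if c.role == "identifier"]


def _canon(value: str) -> str:
    return value.strip().lower()


def canonical_category(column: str, value: str) -> str | None:
    """Map a raw cell to its canonical category string, or None if unknown.

    Matching is case-insensitive and whitespace-insensitive because the
    source data capitalizes inconsistently ('Yes'/'yes').
    """
    spec = column_spec(column)
    if spec.allowed_values is None:
        return value
    table = {_canon(v): v for v in spec.allowed_values}
    return table.get(_canon(value))


# --------------------------------------------------------------------------
# PatientTable
# --------------------------------------------------------------------------


@dataclass
class PatientTable:
    """A validated patient record table backed by a pandas DataFrame.

    Cells of numeric columns are float (NaN = null); all other cells are
    strings or ``pd.NA``. A table may hold a *subset* of the registered
    columns (e.g. after feature dropping) but must always retain both
    target columns.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        for target in TARGET_COLUMNS:
            if target not in self.df.columns:
                raise SchemaError(f"mandatory target column {target!r} is missing")
        unknown = [c for c in self.df.columns if c not in _ALL_SPECS]
        if unknown:
            raise SchemaError(f"unregistered columns: {unknown}")
        self.df = self.df.reset_index(drop=True)

    @property
    def n_rows(self) -> int:
        return len(self.df)

    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    def is_full_schema(self) -> bool:
        """True when all 44 registered columns are present."""
        return all(name in self.df.columns for name in COLUMN_NAMES)

    def equals(self, other: "PatientTable") -> bool:
        if self.columns != other.columns or self.n_rows != other.n_rows:
            return False
        for col in self.columns:
            a, b = self.df[col], other.df[col]
            if column_spec(col).value_kind == "numeric":
                if not np.array_equal(
                    a.to_numpy(dtype=float), b.to_numpy(dtype=float), equal_nan=True
                ):
                    return False
            else:
                if not a.fillna("").astype(str).equals(b.fillna("").astype(str)):
                    return False
        return True


def _coerce_columns(df: pd.DataFrame, strict: bool) -> pd.DataFrame:
    """Normalize headers, drop/reject unknown columns, parse numerics."""
    alias = {name.strip(): name for name in _ALL_SPECS}
    rename = {}
    for col in df.columns:
        stripped = str(col).strip()
        if stripped in alias and col != alias[stripped]:
            rename[col] = alias[stripped]
    if rename:
        df = df.rename(columns=rename)

    unknown = [c for c in df.columns if c not in _ALL_SPECS]
    if unknown:
        if strict:
            raise SchemaError(f"unknown columns in strict mode: {unknown}")
        logger.warning("ignoring unknown columns: %s", unknown)
        df = df.drop(columns=unknown)

    cell_errors: list[tuple[int, str]] = []
    for col in df.columns:
        spec = _ALL_SPECS[col]
        if spec.value_kind == "numeric":
            parsed = pd.to_numeric(df[col], errors="coerce")
            bad = parsed.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
            if bad.any():
                cell_errors.extend((int(i), col) for i in df.index[bad])
            df[col] = parsed.astype(float)
    if cell_errors:
        head = ", ".join(f"(row {r}, {c!r})" for r, c in cell_errors[:10])
        raise CellError(
            f"{len(cell_errors)} unparseable numeric cell(s): {head}", cell_errors
        )
    return df


def _validate_targets(df: pd.DataFrame) -> None:
    for target, classes in ((TARGET_DISORDER, DISORDER_CLASSES), (TARGET_SUBCLASS, SUBCLASS_CLASSES)):
        if target not in df.columns:
            raise SchemaError(f"mandatory target column {target!r} is missing")
        values = df[target].dropna()
        canon = {v.strip().lower() for v in classes}
        bad = sorted({v for v in values if str(v).strip().lower() not in canon})
        if bad:
            raise SchemaError(f"unknown {target!r} class value(s): {bad[:5]}")


def from_dataframe(df: pd.DataFrame, strict: bool = True) -> PatientTable:
    """Build a validated PatientTable from an in-memory frame."""
    df = df.copy()
    df = df.replace({"": pd.NA})
    df = _coerce_columns(df, strict)
    _validate_targets(df)
    return PatientTable(df)


def read_patient_csv(path, strict: bool = False) -> PatientTable:
    """Read a patient table from CSV.

    Empty cells become nulls; numeric columns are parsed to float with
    cell-level error reporting; unknown columns raise in strict mode and
    are dropped with a warning otherwise.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.replace({"": pd.NA})
    df = _coerce_columns(df, strict)
    _validate_targets(df)
    return PatientTable(df)


def write_patient_csv(table: PatientTable, path) -> None:
    """Write a patient table to CSV (empty string encodes null)."""
    out = table.df.copy()
    for col in out.columns:
        if column_spec(col).value_kind == "numeric":
            # render integral floats without a trailing .0 so round trips
            # are byte-stable regardless of how the value was produced
            out[col] = out[col].map(
                lambda v: ""
                if pd.isna(v)
                else (str(int(v)) if float(v).is_integer() else repr(float(v)))
            )
    out.to_csv(path, index=False, na_rep="")


def class_distribution(table: PatientTable) -> dict[str, dict[str, int]]:
    """Per-class counts of non-null values for both targets.

    Every registered class appears in the result, zero counts included.
    """
    result: dict[str, dict[str, int]] = {}
    for target, classes in ((TARGET_DISORDER, DISORDER_CLASSES), (TARGET_SUBCLASS, SUBCLASS_CLASSES)):
        counts = {c: 0 for c in classes}
        canon = {c.strip().lower(): c for c in classes}
        for v in table.df[target].dropna():
            counts[canon[str(v).strip().lower()]] += 1
        result[target] = counts
    return result
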