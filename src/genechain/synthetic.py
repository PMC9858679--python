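"""Schema-faithful synthetic patient tables with planted label structure.

Every generated table carries all 44 registered columns with category
alphabets matching the encoder, a disorder label drawn from configurable
priors, and a subclass nested in a disorder→subclass hierarchy (three
disjoint groups of three). Four scenarios control how features relate to
labels:

``separable``
    Deterministic one-hot gene indicators plus disjoint numeric bands —
    every reasonable learner can reach 100% test accuracy.
``noisy_linear``
    Features are noisy conditional draws around class-specific centers;
    the disorder signal is moderately strong, the within-group subclass
    signal deliberately weak, so subclass prediction benefits from
    conditioning on the disorder.
``nonlinear_interaction``
    Labels depend on XORs of binary genes and sign-of-product rules over
    numeric pairs: no single feature carries marginal signal, so linear
    learners fail while tree ensembles succeed.
``independent_labels``
    The subclass is drawn independently of the disorder (hierarchy
    ignored) with its own feature signal.

Numeric marginals are stylized (blood cell count ≈ N(4.9, 0.35) clipped to
4.2–5.6 mcL, white blood cell count on 0–12, patient age within 15 years),
not fitted to any real dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from genechain import schema
from genechain.errors import ConfigError
from genechain.schema import (
    COLUMN_REGISTRY,
    DISORDER_CLASSES,
    REFERENCE_N_ROWS,
    SUBCLASS_CLASSES,
    TARGET_COLUMNS,
    TARGET_DISORDER,
    TARGET_SUBCLASS,
    PatientTable,
    from_dataframe,
)

SCENARIOS = ("separable", "noisy_linear", "nonlinear_interaction", "independent_labels")

_YES_NO = np.array(["Yes", "No"])

_FIRST_NAMES = ("Aiden", "Bela", "Chen", "Dara", "Emil", "Fay", "Goran", "Hana")
_FAMILY_NAMES = ("Silva", "Khan", "Osei", "Novak", "Reyes", "Tanaka", "Weber", "Larsen")
_INSTITUTES = ("Central Genomics Institute", "Regional Medical Center", "University Hospital")
_PLACES = ("City Hospital", "Rural Clinic", "Home", "District Hospital")


def default_hierarchy() -> dict[int, tuple[int, int, int]]:
    """Disorder-code → subclass-code partition (three groups of three).

    Mitochondrial: Leber's hereditary optic neuropathy, Leigh syndrome,
    mitochondrial myopathy. Multifactorial: diabetes, cancer, Alzheimer's.
    Single-gene: cystic fibrosis, Tay-Sachs, hemochromatosis.
    """
    return {0: (0, 2, 7), 1: (1, 3, 8), 2: (4, 5, 6)}


def validate_hierarchy(hierarchy: dict[int, tuple[int, ...]]) -> dict[int, tuple[int, ...]]:
    """Check the hierarchy partitions the 9 subclasses into 3 groups of 3."""
    if sorted(hierarchy) != [0, 1, 2]:
        raise ConfigError("hierarchy must map disorder codes 0, 1, 2")
    groups = [tuple(int(s) for s in hierarchy[k]) for k in range(3)]
    if any(len(g) != 3 for g in groups):
        raise ConfigError("each hierarchy group must have exactly 3 subclasses")
    flat = sorted(s for g in groups for s in g)
    if flat != list(range(9)):
        raise ConfigError("hierarchy must partition subclass codes 0..8 exactly once")
    return {k: groups[k] for k in range(3)}


def emulate_missingness_profile() -> dict[str, float]:
    """Per-column null probability derived from the reference non-null counts."""
    return {
        c.name: 1.0 - c.observed_count / REFERENCE_N_ROWS for c in COLUMN_REGISTRY
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator configuration.

    ``missingness`` maps column name → null probability; labels are exempt
    unless ``allow_label_nulls`` is set. ``margin`` widens class gaps in the
    separable scenario; ``noise`` scales feature noise elsewhere.
    """

    n_rows: int = 1000
    disorder_priors: tuple[float, float, float] = (0.512, 0.104, 0.384)
    hierarchy: dict[int, tuple[int, ...]] | None = None
    missingness: dict[str, float] | None = None
    scenario: str = "noisy_linear"
    margin: float = 1.0
    noise: float = 1.0
    allow_label_nulls: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1:
            raise ConfigError("n_rows must be positive")
        if self.scenario not in SCENARIOS:
            raise ConfigError(f"unknown scenario {self.scenario!r}; one of {SCENARIOS}")
        priors = np.asarray(self.disorder_priors, dtype=float)
        if priors.shape != (3,) or (priors < 0).any() or abs(priors.sum() - 1.0) > 1e-12:
            raise ConfigError("disorder_priors must be 3 non-negative reals summing to 1")
        if self.hierarchy is not None:
            validate_hierarchy(self.hierarchy)
        if self.missingness:
            for col, p in self.missingness.items():
                schema.column_spec(col)  # raises on unknown column
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"missingness for {col!r} must lie in [0,1]")


def _round4(x: np.ndarray) -> np.ndarray:
    # fixed precision keeps CSV round trips byte-stable
    return np.round(np.asarray(x, dtype=float), 4)


def _base_frame(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Plausible iid draws for every column; scenarios overwrite the signals."""
    df = pd.DataFrame(index=range(n))
    df["Patient Id"] = [f"PID{i:06d}" for i in range(n)]
    df["Patient Age"] = _round4(rng.uniform(0, 14, n))
    df["Genes in mother's side"] = rng.choice(_YES_NO, n)
    df["Inherited from father"] = rng.choice(_YES_NO, n)
    df["Maternal gene"] = rng.choice(_YES_NO, n)
    df["Paternal gene"] = rng.choice(_YES_NO, n)
    df["Blood cell count (mcL)"] = _round4(np.clip(rng.normal(4.9, 0.35, n), 4.2, 5.6))
    df["Patient First Name"] = rng.choice(_FIRST_NAMES, n)
    df["Family Name"] = rng.choice(_FAMILY_NAMES, n)
    df["Father's name"] = rng.choice(_FIRST_NAMES, n)
    df["Mother's age"] = _round4(rng.uniform(18, 50, n))
    df["Father's age"] = _round4(rng.uniform(20, 65, n))
    df["Institute Name"] = rng.choice(_INSTITUTES, n)
    df["Location of Institute"] = rng.choice(_PLACES, n)
    df["Status"] = rng.choice(["Alive", "Deceased"], n, p=[0.8, 0.2])
    df["Respiratory Rate (breaths/min)"] = rng.choice(["Normal (30-60)", "Tachypnea"], n)
    df["Heart Rate (rates/min"] = rng.choice(["Normal", "Tachypnea"], n)
    for t in (1, 2, 3, 4, 5):
        df[f"Test {t}"] = _round4(rng.uniform(0, 10, n))
    df["Follow-up"] = rng.choice(["Low", "High"], n)
    df["Gender"] = rng.choice(["Male", "Female", "Ambiguous"], n, p=[0.48, 0.48, 0.04])
    df["Birth asphyxia"] = rng.choice(["No record", "Not available", "No", "Yes"], n)
    df["Autopsy shows birth defect (if applicable)"] = rng.choice(
        ["None", "Not applicable", "No", "Yes"], n
    )
    df["Place of birth"] = rng.choice(_PLACES, n)
    df["Folic acid details (peri-conceptional)"] = rng.choice(_YES_NO, n)
    df["H/O serious maternal illness"] = rng.choice(_YES_NO, n)
    df["H/O radiation exposure (X-ray)"] = rng.choice(["Yes", "No", "Not applicable"], n)
    df["H/O substance abuse"] = rng.choice(["Yes", "No", "Not applicable"], n)
    df["Assisted conception IVF/ART"] = rng.choice(_YES_NO, n)
    df["History of anomalies in previous pregnancies"] = rng.choice(_YES_NO, n)
    df["No. of previous abortion"] = rng.integers(0, 5, n).astype(float)
    df["Birth defects"] = rng.choice(["Singular", "Multiple"], n)
    df["White Blood cell count (thousand per microliter)"] = _round4(rng.uniform(0, 12, n))
    df["Blood test result"] = rng.choice(["normal", "abnormal"], n)
    for s in range(1, 6):
        df[f"Symptom {s}"] = rng.integers(0, 2, n).astype(float)
    return df


def _yes_iff(flag: np.ndarray) -> np.ndarray:
    return np.where(flag, "Yes", "No")


def _flip(values: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Flip Yes<->No with probability p."""
    flip = rng.random(len(values)) < p
    flipped = np.where(values == "Yes", "No", "Yes")
    return np.where(flip, flipped, values)


_WBC_CENTERS = np.array([2.0, 6.0, 10.0])
_AGE_CENTERS = np.array([2.0, 7.0, 12.0])


def _apply_separable(df, disorder, j, config, rng):
    half = 1.5 / (1.0 + config.margin)
    df["Genes in mother's side"] = _yes_iff(disorder == 0)
    df["Inherited from father"] = _yes_iff(disorder == 1)
    df["Maternal gene"] = _yes_iff(disorder == 2)
    df["Paternal gene"] = _yes_iff(j == 0)
    df["H/O serious maternal illness"] = _yes_iff(j == 1)
    df["Folic acid details (peri-conceptional)"] = _yes_iff(j == 2)
    n = len(df)
    # jitter on a discrete grid so decision thresholds learned on any train
    # subset generalize exactly: test values never fall between a learned
    # threshold and the training support
    jitter = np.array([-half, 0.0, half])
    df["White Blood cell count (thousand per microliter)"] = _round4(
        _WBC_CENTERS[disorder] + rng.choice(jitter, n)
    )
    df["Patient Age"] = _round4(_AGE_CENTERS[j] + rng.choice(jitter / 2, n))
    return disorder, j


def _apply_noisy_linear(df, disorder, j, config, rng):
    n = len(df)
    noise = config.noise
    df["White Blood cell count (thousand per microliter)"] = _round4(
        np.clip(_WBC_CENTERS[disorder] + rng.normal(0, 1.2 * noise, n), 0, 12)
    )
    p_flip_d = min(0.4, 0.10 * noise)
    df["Genes in mother's side"] = _flip(_yes_iff(disorder == 0), p_flip_d, rng)
    df["Inherited from father"] = _flip(_yes_iff(disorder == 1), p_flip_d, rng)
    df["Maternal gene"] = _flip(_yes_iff(disorder == 2), p_flip_d, rng)
    # within-group signal is deliberately weak: heavy age overlap, noisy flags
    df["Patient Age"] = _round4(
        np.clip(_AGE_CENTERS[j] + rng.normal(0, 3.0 * noise, n), 0, 14)
    )
    p_flip_j = min(0.45, 0.35 * noise)
    df["Paternal gene"] = _flip(_yes_iff(j == 0), p_flip_j, rng)
    df["H/O serious maternal illness"] = _flip(_yes_iff(j == 1), p_flip_j, rng)
    df["Folic acid details (peri-conceptional)"] = _flip(_yes_iff(j == 2), p_flip_j, rng)
    return disorder, j


def _apply_nonlinear(df, disorder, j, config, rng):
    n = len(df)
    mg = rng.integers(0, 2, n)
    pg = rng.integers(0, 2, n)
    gms = rng.integers(0, 2, n)
    iff = rng.integers(0, 2, n)
    wbc = _round4(rng.uniform(0, 12, n))
    age = _round4(rng.uniform(0, 14, n))
    bcc = _round4(np.clip(rng.normal(4.9, 0.35, n), 4.2, 5.6))
    mother_age = _round4(rng.uniform(18, 50, n))

    df["Maternal gene"] = _yes_iff(mg == 1)
    df["Paternal gene"] = _yes_iff(pg == 1)
    df["Genes in mother's side"] = _yes_iff(gms == 1)
    df["Inherited from father"] = _yes_iff(iff == 1)
    df["White Blood cell count (thousand per microliter)"] = wbc
    df["Patient Age"] = age
    df["Blood cell count (mcL)"] = bcc
    df["Mother's age"] = mother_age

    u = mg ^ pg
    v = ((wbc - 6.0) * (age - 7.0) > 0).astype(int)
    disorder = u + v
    u2 = gms ^ iff
    v2 = ((bcc - 4.9) * (mother_age - 34.0) > 0).astype(int)
    j = u2 + v2

    flip = 0.05 * config.noise
    if flip > 0:
        relab = rng.random(n) < flip
        disorder = np.where(relab, rng.integers(0, 3, n), disorder)
        relab_j = rng.random(n) < flip
        j = np.where(relab_j, rng.integers(0, 3, n), j)
    return disorder.astype(int), j.astype(int)


def _apply_independent(df, disorder, subclass, config, rng):
    n = len(df)
    noise = config.noise
    df["White Blood cell count (thousand per microliter)"] = _round4(
        np.clip(_WBC_CENTERS[disorder] + rng.normal(0, 1.2 * noise, n), 0, 12)
    )
    p_flip_d = min(0.4, 0.10 * noise)
    df["Genes in mother's side"] = _flip(_yes_iff(disorder == 0), p_flip_d, rng)
    df["Inherited from father"] = _flip(_yes_iff(disorder == 1), p_flip_d, rng)
    df["Maternal gene"] = _flip(_yes_iff(disorder == 2), p_flip_d, rng)
    # subclass signal independent of the disorder
    df["Father's age"] = _round4(
        np.clip(22.5 + subclass * 4.5 + rng.normal(0, 2.2 * noise, n), 20, 65)
    )
    return disorder, subclass


def generate(config: SyntheticConfig) -> tuple[PatientTable, pd.DataFrame]:
    """Generate a patient table and its aligned ground-truth sidecar.

    Returns ``(table, ground_truth)`` where the sidecar holds the
    generating ``disorder_code``, ``subclass_code`` and within-group index
    ``group_index`` (−1 for independent_labels) for every row, recorded
    before missingness injection.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_rows
    hierarchy = validate_hierarchy(config.hierarchy or default_hierarchy())
    group_table = np.array([hierarchy[k] for k in range(3)])  # (3, 3) codes

    disorder = rng.choice(3, size=n, p=np.asarray(config.disorder_priors, dtype=float))
    df = _base_frame(n, rng)

    if config.scenario == "separable":
        j = rng.integers(0, 3, n)
        disorder, j = _apply_separable(df, disorder, j, config, rng)
        subclass = group_table[disorder, j]
    elif config.scenario == "noisy_linear":
        j = rng.integers(0, 3, n)
        disorder, j = _apply_noisy_linear(df, disorder, j, config, rng)
        subclass = group_table[disorder, j]
    elif config.scenario == "nonlinear_interaction":
        disorder, j = _apply_nonlinear(df, disorder, None, config, rng)
        subclass = group_table[disorder, j]
    else:  # independent_labels
        subclass = rng.integers(0, 9, n)
        disorder, subclass = _apply_independent(df, disorder, subclass, config, rng)
        j = np.full(n, -1)

    df[TARGET_DISORDER] = np.asarray(DISORDER_CLASSES, dtype=object)[disorder]
    df[TARGET_SUBCLASS] = np.asarray(SUBCLASS_CLASSES, dtype=object)[subclass]
    df = df[list(schema.COLUMN_NAMES)]

    ground_truth = pd.DataFrame(
        {
            "row": np.arange(n),
            "disorder_code": disorder,
            "subclass_code": subclass,
            "group_index": j,
        }
    )

    if config.missingness:
        for col, p in config.missingness.items():
            if p <= 0 or col not in df.columns:
                continue
            if col in TARGET_COLUMNS and not config.allow_label_nulls:
                continue
            mask = rng.random(n) < p
            if mask.any():
                df[col] = df[col].astype(object)
                df.loc[mask, col] = pd.NA

    return from_dataframe(df, strict=True), ground_truth


def write_ground_truth(ground_truth: pd.DataFrame, path) -> None:
    ground_truth.to_csv(path, index=False)


def read_ground_truth(path) -> pd.DataFrame:
    return pd.read_csv(path)
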