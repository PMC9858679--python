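import logging

import numpy as np
import pandas as pd
import pytest

from genechain.errors import DataError, EncodingError
from genechain.preprocess import (
    CODE_ALPHABET,
    DROP_COLUMNS,
    ENCODING_MAPS,
    SplitSpec,
    balance_undersample,
    drop_noncontributing,
    encode_features,
    encode_targets,
    encoding_maps_from_text,
    encoding_maps_to_text,
    indicator_to_labels,
    labels_to_indicator,
    prepare_dataset,
    train_test_split,
)
from genechain.schema import DISORDER_CLASSES, SUBCLASS_CLASSES, from_dataframe
from genechain.synthetic import SyntheticConfig, generate


class TestDrop:
    def test_drop_list_is_the_thirteen_named_columns(self):
        assert len(DROP_COLUMNS) == 13
        assert "Test 4" not in DROP_COLUMNS
        assert {"Test 1", "Test 2", "Test 3", "Test 5"} <= set(DROP_COLUMNS)
        assert "Autopsy shows birth defect (if applicable)" in DROP_COLUMNS

    def test_retains_test4_drops_test2(self, small_table):
        out = drop_noncontributing(small_table)
        assert "Test 4" in out.columns
        assert "Test 2" not in out.columns
        assert "Patient Id" not in out.columns

    def test_idempotent(self, small_table):
        once = drop_noncontributing(small_table)
        twice = drop_noncontributing(once)
        assert once.columns == twice.columns
        assert once.equals(twice)

    def test_absent_column_warns(self, small_table, caplog):
        partial = from_dataframe(small_table.df.drop(columns=["Family Name"]))
        with caplog.at_level(logging.WARNING, logger="genechain.preprocess"):
            out = drop_noncontributing(partial)
        assert "Family Name" not in out.columns
        assert any("Family Name" in r.message for r in caplog.records)


class TestEncodeFeatures:
    @pytest.fixture()
    def encoded(self, small_table):
        return encode_features(drop_noncontributing(small_table))

    def test_code_alphabet(self):
        for mapping in ENCODING_MAPS.values():
            assert set(mapping.values()) <= CODE_ALPHABET

    def test_feature_count_from_full_schema(self, encoded):
        # 44 columns - 2 targets - 12 dropped Table-format columns = 30
        assert encoded.n_features == 30

    @pytest.mark.parametrize(
        "column,value,code",
        [
            ("Maternal gene", "Yes", 1),
            ("Maternal gene", "No", 0),
            ("H/O substance abuse", "Not applicable", -1),
            ("H/O radiation exposure (X-ray)", "Not applicable", -1),
            ("Gender", "Ambiguous", 2),
            ("Gender", "Male", 0),
            ("Gender", "Female", 1),
            ("Birth asphyxia", "No record", 0),
            ("Birth asphyxia", "Not available", 0),
            ("Birth asphyxia", "Yes", 1),
            ("Status", "Deceased", 0),
            ("Status", "Alive", 1),
            ("Respiratory Rate (breaths/min)", "Normal (30-60)", 0),
            ("Respiratory Rate (breaths/min)", "Tachypnea", 1),
            ("Heart Rate (rates/min", "Normal", 0),
            ("Follow-up", "Low", 0),
            ("Follow-up", "High", 1),
            ("Birth defects", "Singular", 0),
            ("Birth defects", "Multiple", 1),
            ("Blood test result", "normal", 0),
            ("Blood test result", "abnormal", 1),
        ],
    )
    def test_printed_codes(self, small_table, column, value, code):
        df = drop_noncontributing(small_table).df.copy()
        df[column] = value
        got = encode_features(from_dataframe(df))
        col_idx = got.feature_names.index(column)
        assert np.all(got.values[:, col_idx] == code)

    def test_null_numeric_filled_with_zero(self, small_table):
        df = drop_noncontributing(small_table).df.copy()
        df["Mother's age"] = pd.NA
        got = encode_features(from_dataframe(df))
        assert np.all(got.values[:, got.feature_names.index("Mother's age")] == 0)

    def test_null_categorical_filled_with_zero(self, small_table):
        df = drop_noncontributing(small_table).df.copy()
        df["Maternal gene"] = pd.NA
        got = encode_features(from_dataframe(df))
        assert np.all(got.values[:, got.feature_names.index("Maternal gene")] == 0)

    def test_no_nulls_remain(self, encoded):
        assert np.isfinite(encoded.values).all()

    def test_unseen_category_raises_with_names(self, small_table):
        df = drop_noncontributing(small_table).df.copy()
        df["Follow-up"] = df["Follow-up"].astype(object)
        df.loc[0, "Follow-up"] = "Medium"
        # schema validation is bypassed to exercise the encoder's own guard
        table = drop_noncontributing(small_table)
        table.df["Follow-up"] = df["Follow-up"]
        with pytest.raises(EncodingError) as exc_info:
            encode_features(table)
        assert exc_info.value.column == "Follow-up"
        assert exc_info.value.value == "Medium"

    def test_deterministic(self, small_table):
        dropped = drop_noncontributing(small_table)
        a = encode_features(dropped)
        b = encode_features(dropped)
        assert np.array_equal(a.values, b.values)
        assert a.feature_names == b.feature_names


class TestEncodeTargets:
    def test_code_convention(self, small_table):
        df = small_table.df.iloc[:1].copy()
        df["Genetic Disorder"] = DISORDER_CLASSES[0]  # mitochondrial
        df["Disorder Subclass"] = SUBCLASS_CLASSES[0]  # Leber's
        enc = encode_targets(from_dataframe(df))
        assert enc.labels.tolist() == [[0, 0]]
        assert enc.indicator.sum() == 2

    def test_indicator_rows_sum_to_two(self, small_table):
        enc = encode_targets(small_table)
        assert np.all(enc.indicator.sum(axis=1) == 2)

    def test_null_subclass_rows_excluded(self, small_table):
        df = small_table.df.copy()
        df.loc[0, "Disorder Subclass"] = pd.NA
        enc = encode_targets(from_dataframe(df))
        assert enc.n_excluded == 1
        assert len(enc.labels) == len(df) - 1
        assert 0 not in enc.kept_index

    def test_indicator_round_trip(self, small_table):
        enc = encode_targets(small_table)
        assert np.array_equal(indicator_to_labels(enc.indicator), enc.labels)


class TestBalance:
    def _labels(self, counts):
        disorder = np.repeat([0, 1, 2], counts)
        subclass = np.zeros_like(disorder)
        return np.column_stack([disorder, subclass])

    def test_reduces_to_min_count(self):
        y = self._labels([102, 20, 76])
        X = np.arange(len(y), dtype=float)[:, None]
        Xb, yb = balance_undersample(X, y, seed=0)
        counts = np.bincount(yb[:, 0])
        assert counts.tolist() == [20, 20, 20]

    def test_already_equal_unchanged(self):
        y = self._labels([5, 5, 5])
        X = np.arange(15, dtype=float)[:, None]
        Xb, yb = balance_undersample(X, y, seed=1)
        assert np.array_equal(np.sort(Xb.ravel()), X.ravel())

    def test_same_seed_identical_selection(self):
        y = self._labels([50, 9, 30])
        X = np.arange(len(y), dtype=float)[:, None]
        a = balance_undersample(X, y, seed=42)
        b = balance_undersample(X, y, seed=42)
        assert np.array_equal(a[0], b[0])

    def test_empty_class_errors(self):
        y = self._labels([5, 0, 5])
        X = np.zeros((10, 1))
        with pytest.raises(DataError):
            balance_undersample(X, y, seed=0)


class TestSplit:
    def _data(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 4))
        y = np.column_stack([rng.integers(0, 3, n), rng.integers(0, 9, n)])
        return X, y

    def test_sizes(self):
        X, y = self._data(100)
        Xtr, ytr, Xte, yte = train_test_split(X, y, SplitSpec(0.8, seed=0, stratified=False))
        assert len(Xtr) == 80 and len(Xte) == 20

    def test_disjoint_exhaustive(self):
        X, y = self._data(101)
        Xtr, ytr, Xte, yte = train_test_split(X, y, SplitSpec(0.7, seed=1))
        assert len(Xtr) + len(Xte) == 101
        combined = np.vstack([Xtr, Xte])
        assert np.array_equal(
            np.sort(combined, axis=0), np.sort(X, axis=0)
        )

    def test_deterministic(self):
        X, y = self._data(80)
        a = train_test_split(X, y, SplitSpec(0.8, seed=9))
        b = train_test_split(X, y, SplitSpec(0.8, seed=9))
        for u, v in zip(a, b):
            assert np.array_equal(u, v)

    def test_stratified_within_one_sample(self):
        rng = np.random.default_rng(3)
        n = 900
        y = np.column_stack([rng.integers(0, 3, n), np.zeros(n, dtype=int)])
        y[:, 1] = [np.random.default_rng(i).integers(0, 3) for i in range(n)]
        X = rng.normal(size=(n, 2))
        Xtr, ytr, Xte, yte = train_test_split(X, y, SplitSpec(0.8, seed=3, stratified=True))
        joint_all = y[:, 0] * 100 + y[:, 1]
        joint_tr = ytr[:, 0] * 100 + ytr[:, 1]
        for key in np.unique(joint_all):
            total = np.sum(joint_all == key)
            in_train = np.sum(joint_tr == key)
            assert abs(in_train - 0.8 * total) <= 1

    def test_singleton_stratum_warns(self, caplog):
        X = np.zeros((5, 2))
        y = np.array([[0, 0], [0, 0], [0, 0], [0, 0], [2, 8]])
        with caplog.at_level(logging.WARNING, logger="genechain.preprocess"):
            train_test_split(X, y, SplitSpec(0.8, seed=0, stratified=True))
        assert any("single sample" in r.message for r in caplog.records)

    def test_invalid_fraction(self):
        with pytest.raises(DataError):
            SplitSpec(1.2)

    def test_too_few_rows(self):
        with pytest.raises(DataError):
            train_test_split(np.zeros((1, 2)), np.zeros((1, 2), int), SplitSpec(0.5))


class TestEncodingMapExport:
    def test_round_trip(self):
        text = encoding_maps_to_text()
        assert encoding_maps_from_text(text) == ENCODING_MAPS

    def test_format_is_auditable(self):
        assert "Gender::Ambiguous=2" in encoding_maps_to_text()


class TestPrepareDataset:
    def test_pipeline_shapes(self, small_table):
        X, targets = prepare_dataset(small_table)
        assert X.n_rows == len(targets.labels)
        assert X.n_features == 30
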