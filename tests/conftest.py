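import warnings

import numpy as np
import pandas as pd
import pytest

from genechain.schema import (
    COLUMN_NAMES,
    DISORDER_CLASSES,
    SUBCLASS_CLASSES,
    from_dataframe,
)
from genechain.synthetic import SyntheticConfig, generate

warnings.filterwarnings("ignore", category=FutureWarning, module="sklearn")


def make_minimal_frame(n_rows: int = 3) -> pd.DataFrame:
    """A tiny full-schema frame with deterministic contents."""
    rng = np.random.default_rng(0)
    config = SyntheticConfig(n_rows=n_rows, seed=0)
    table, _ = generate(config)
    return table.df.copy()


@pytest.fixture(scope="session")
def small_table():
    table, _ = generate(SyntheticConfig(n_rows=30, seed=7))
    return table


@pytest.fixture(scope="session")
def separable_split():
    """Encoded train/test partition of a wide-margin separable table."""
    from genechain.preprocess import SplitSpec, prepare_dataset, train_test_split

    table, _ = generate(
        SyntheticConfig(n_rows=1200, scenario="separable", margin=3.0, seed=11)
    )
    X, targets = prepare_dataset(table)
    X_tr, y_tr, X_te, y_te = train_test_split(
        X.values, targets.labels, SplitSpec(0.8, seed=11)
    )
    return X_tr, y_tr, X_te, y_te


def random_indicator_pair(rng: np.random.Generator, n: int, L: int = 12):
    return rng.integers(0, 2, (n, L)), rng.integers(0, 2, (n, L))
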