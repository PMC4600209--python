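import matplotlib
import numpy as np
import pandas as pd
import pytest

matplotlib.use("Agg")

from rehabrank.data_model import Cohort, Item, ItemDictionary, OUTCOME_COL, DesignMatrix
from rehabrank.matching import StratumTable


@pytest.fixture(scope="session")
def ca_table() -> StratumTable:
    return StratumTable.ca_population()


def make_cohort(df: pd.DataFrame, items: list[Item]) -> Cohort:
    """Assemble a cohort from a plain frame (adds client ids if absent)."""
    if df.index.name != "client_id":
        df = df.copy()
        df.index = pd.Index([f"c{i}" for i in range(len(df))], name="client_id")
    return Cohort(df, ItemDictionary(items))


def design_from_matrix(X: np.ndarray, groups: list[int], codes: list[str]) -> DesignMatrix:
    """Wrap a raw numeric matrix as a standardized design for solver tests."""
    X = np.asarray(X, dtype=float)
    center = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    const = sd == 0
    scale = np.where(const, 1.0, sd)
    return DesignMatrix(
        X=(X - center) / scale,
        groups=np.asarray(groups),
        group_codes=codes,
        column_labels=[f"x{j}" for j in range(X.shape[1])],
        constant_mask=const,
        standardized=True,
        center=center,
        scale=scale,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20250920)
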