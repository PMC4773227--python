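import numpy as np
import pandas as pd
import pytest

from cardiopanel import (CASE, CONTROL, ExpressionDataset, SyntheticConfig,
                         generate_dataset)


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort: 1000 probes, 15+15 samples, 50 planted."""
    return generate_dataset(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def planted_cohort():
    """Smaller cohort with a strong planted signal for optimiser tests."""
    return generate_dataset(SyntheticConfig(n_probes=200, n_de=10, seed=3))


@pytest.fixture()
def separable_dataset():
    """Two tight, widely separated clusters: LOOCV must score 100%."""
    rng = np.random.default_rng(5)
    n_per, p = 8, 6
    case = rng.normal(0.0, 0.05, size=(p, n_per))
    control = rng.normal(4.0, 0.05, size=(p, n_per))
    values = pd.DataFrame(
        np.hstack([case, control]),
        index=[f"PS{i}" for i in range(p)],
        columns=[f"S{j}" for j in range(2 * n_per)],
    )
    labels = pd.Series([CASE] * n_per + [CONTROL] * n_per, index=values.columns)
    return ExpressionDataset(values=values, labels=labels, name="separable")


def make_dataset(matrix, labels, probe_prefix="PS", batch=None):
    """Small helper to build a dataset from a plain array + label list."""
    matrix = np.asarray(matrix, dtype=float)
    values = pd.DataFrame(
        matrix,
        index=[f"{probe_prefix}{i}" for i in range(matrix.shape[0])],
        columns=[f"S{j}" for j in range(matrix.shape[1])],
    )
    lab = pd.Series(labels, index=values.columns)
    b = None if batch is None else pd.Series(batch, index=values.columns)
    return ExpressionDataset(values=values, labels=lab, batch=b)
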