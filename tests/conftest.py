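import numpy as np
import pandas as pd
import pytest

from gutsem.data_io import CountTable, SampleMetadata
from gutsem.synthetic_data import SyntheticConfig, generate


@pytest.fixture
def small_counts() -> CountTable:
    return CountTable(
        ["s1", "s2", "s3"],
        ["gA", "gB", "gC", "gD"],
        np.array([[5, 0, 3, 2], [1, 1, 1, 1], [0, 9, 0, 4]], dtype=np.int64),
    )


@pytest.fixture
def small_meta() -> list[SampleMetadata]:
    return [
        SampleMetadata("s1", "male", "case", age=71.0, bmi=22.1),
        SampleMetadata("s2", "female", "case", age=74.0, bmi=20.5),
        SampleMetadata("s3", "male", "control", age=70.0, bmi=23.0),
        SampleMetadata("s4", "female", "control", age=72.0, bmi=21.0),
    ]


@pytest.fixture(scope="session")
def planted_dataset():
    """One moderately sized planted-signal dataset shared across tests."""
    return generate(SyntheticConfig(n_case=20, n_control=20, seed=42))


def one_factor_data(n: int, loadings, seed: int = 0, noise_cols: int = 0):
    """Sampled indicators from a one-factor model plus optional pure noise."""
    loadings = np.asarray(loadings, dtype=float)
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n)
    X = loadings[None, :] * z[:, None] + \
        np.sqrt(1 - loadings ** 2)[None, :] * rng.normal(size=(n, len(loadings)))
    cols = [f"c{i}" for i in range(len(loadings))]
    if noise_cols:
        X = np.hstack([X, rng.normal(size=(n, noise_cols))])
        cols += [f"noise{i}" for i in range(noise_cols)]
    return pd.DataFrame(X, columns=cols), z
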