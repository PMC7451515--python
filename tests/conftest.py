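import numpy as np
import pytest

from elicitopt.anfis import AnfisConfig, train_hybrid
from elicitopt.data_model import to_design_matrix
from elicitopt.pipeline import split_train_test_matrix
from elicitopt.synthetic import DesignSpec, SyntheticSurfaceSpec, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """Default noisy factorial dataset (240 rows, CE, seed 0)."""
    return generate_dataset(DesignSpec(), SyntheticSurfaceSpec(), seed=0)


@pytest.fixture(scope="session")
def default_matrix(default_dataset):
    return to_design_matrix(default_dataset, "CE")


@pytest.fixture(scope="session")
def default_split(default_matrix):
    return split_train_test_matrix(default_matrix.n, 0.75, seed=0)


@pytest.fixture(scope="session")
def trained_anfis(default_matrix, default_split):
    """ANFIS fitted on the default training subset (shared, read-only)."""
    tr = list(default_split.train_indices)
    return train_hybrid(AnfisConfig(), default_matrix.X[tr],
                        default_matrix.y[tr])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
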