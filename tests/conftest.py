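import numpy as np
import pytest

from qsar_garf.datasets import ActivityVector, DescriptorMatrix, QSARDataset
from qsar_garf.synthetic import SyntheticSpec, generate_qsar


@pytest.fixture(scope="session")
def default_problem():
    """The default synthetic study conditions (n=150, p=100, R^2 = 0.8)."""
    return generate_qsar(SyntheticSpec(seed=11))


@pytest.fixture(scope="session")
def small_problem():
    """A fast, fully structured problem for unit tests."""
    spec = SyntheticSpec(n_compounds=80, n_descriptors=20, n_informative=5,
                         n_sparse_columns=3, n_correlated_pairs=3,
                         n_constant_columns=2, seed=5)
    return generate_qsar(spec)


def make_matrix(values, names=None, ids=None) -> DescriptorMatrix:
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return DescriptorMatrix(
        ids or [f"C{i}" for i in range(n)],
        names or [f"D{j}" for j in range(p)],
        values,
    )


def make_dataset(values, y, split=None) -> QSARDataset:
    m = make_matrix(values)
    return QSARDataset(m, ActivityVector(list(m.compound_ids),
                                         np.asarray(y, float)),
                       split or [])
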