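import numpy as np
import pytest

from hifit.data import FeatureMatrix, Outcome


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def linear_data(rng):
    """Small n=120, p=12 matrix where features 0-2 drive a linear outcome."""
    n, p = 120, 12
    X = FeatureMatrix(rng.standard_normal((n, p)), [f"f{j}" for j in range(p)])
    beta = np.array([1.5, 1.2, 1.0])
    y = Outcome(X.values[:, :3] @ beta + 0.5 * rng.standard_normal(n))
    return X, y
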