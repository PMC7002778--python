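import logging

import numpy as np
import pytest

from robustpls import RegressionDataset, SineSimConfig, simulate_sine, simulate_sine_test


@pytest.fixture(autouse=True)
def _quiet_irls_logs(caplog):
    # IRLS non-convergence on the sine study is expected (a linear model
    # cannot represent the data); keep the logs out of the test output
    logging.getLogger("robustpls").setLevel(logging.ERROR)
    yield


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def linear_dataset(rng):
    """Well-conditioned linear data: y = Xb + noise, n=20, m=5."""
    X = rng.normal(size=(20, 5))
    beta = np.array([1.0, -2.0, 0.5, 0.0, 3.0])
    y = X @ beta + 0.05 * rng.normal(size=20)
    return RegressionDataset(X, y)


@pytest.fixture
def sine_train():
    return simulate_sine(SineSimConfig(seed=7))


@pytest.fixture
def sine_test():
    return simulate_sine_test(SineSimConfig(seed=7))


@pytest.fixture
def clean_sine_train():
    return simulate_sine(SineSimConfig(seed=7, outlier_indices=()))
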