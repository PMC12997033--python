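import numpy as np
import pytest

from uqeval import (
    BinaryPredictionSet,
    ClassificationSimConfig,
    GaussianPredictionSet,
    RegressionSimConfig,
    simulate_classification,
    simulate_regression,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_gaussian():
    return GaussianPredictionSet(
        y_true=[1.0, 2.0, 0.5], mu=[1.1, 1.8, 0.2], var=[1.0, 2.0, 0.25]
    ).validate()


@pytest.fixture
def small_binary():
    return BinaryPredictionSet(
        y_true=[1, 0, 1, 0], p1=[0.9, 0.2, 0.6, 0.4]
    ).validate()


@pytest.fixture
def calibrated_regression():
    """Drawn exactly from its own reported Gaussians (c = 1)."""
    return simulate_regression(RegressionSimConfig(n=20_000, seed=101))


@pytest.fixture
def calibrated_classification():
    """Reported probabilities equal the true Bernoulli rates (T_true = 1)."""
    return simulate_classification(ClassificationSimConfig(n=20_000, seed=102))
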