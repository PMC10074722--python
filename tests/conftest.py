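import numpy as np
import pytest

from wavehot.modeling import ClassifierConfig
from wavehot.schema import TRADITIONAL_COLUMNS, FeatureTable
from wavehot.simulate import SimulationConfig, simulate_table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    """13-row labeled traditional-stage table."""
    return simulate_table(SimulationConfig(n_pos=5, n_neg=8, seed=7))


@pytest.fixture
def traditional_table():
    """Default-size (101/170) labeled traditional-stage table."""
    return simulate_table(SimulationConfig(seed=3))


@pytest.fixture
def light_config():
    """Small booster for tests that only need a working classifier."""
    return ClassifierConfig(max_depth=3, num_leaves=8, n_estimators=30, seed=0)


def make_plain_table(X, y=None, prefix="f"):
    """Wrap a raw array as a selected-stage FeatureTable."""
    X = np.asarray(X, dtype=float)
    cols = [f"{prefix}{i}" for i in range(X.shape[1])]
    return FeatureTable(columns=cols, values=X, labels=y, stage="selected")
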