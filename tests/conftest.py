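import numpy as np
import pytest

from maizecast.pipeline import make_synthetic_dataset
from maizecast.synthetic import SyntheticConfig, SyntheticTruth


@pytest.fixture(scope="session")
def small_dataset():
    """Two regions (one unimodal, one bimodal), 10 harvest years, strong
    single-feature signal with mild noise — shared across read-only tests."""
    config = SyntheticConfig(n_regions=2, years=tuple(range(2010, 2020)), seed=11)
    truth = SyntheticTruth(("tas.min01_r",), (-0.6,), "linear", (0.47, 0.01), 0.05, 11)
    return make_synthetic_dataset(config, truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
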