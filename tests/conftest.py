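import numpy as np
import pytest

from topper import benchmark
from topper.synthetic import SimSpec, simulate_dataset


@pytest.fixture(scope="session")
def benchmark_cms():
    return benchmark.confusion_matrices()


@pytest.fixture(scope="session")
def benchmark_regions():
    return benchmark.region_counts()


@pytest.fixture(scope="session")
def small_bundle():
    """A small 5-predictor synthetic dataset for integration tests."""
    spec = SimSpec(n_proteins=30, seed=7)
    return simulate_dataset(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
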