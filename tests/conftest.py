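import numpy as np
import pytest

from amexpand.simulate import SyntheticConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic dataset at the study defaults, shared across tests."""
    return simulate_dataset(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def default_dataset_dir(tmp_path_factory):
    """The same study-default dataset written to disk for I/O and CLI tests."""
    outdir = tmp_path_factory.mktemp("dataset")
    simulate_dataset(SyntheticConfig(seed=1), outdir=outdir)
    return outdir


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
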