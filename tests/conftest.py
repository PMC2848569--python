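import numpy as np
import pytest

from subcell.config import RunConfig
from subcell.synthdata import SyntheticConfig, make_benchmark


@pytest.fixture(scope="session")
def tiny_benchmark():
    """40 proteins, 3 locations, noise-free: fast but fully featured."""
    return make_benchmark(
        SyntheticConfig(n_proteins=40, n_locations=3, orphan_frac=0.3, seed=7)
    )


@pytest.fixture(scope="session")
def run_config():
    return RunConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
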