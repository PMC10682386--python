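import numpy as np
import pytest

from scdreamer_kit import make_spec, simulate


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small separable 3-batch dataset used by fast model tests."""
    spec = make_spec(n_cells=400, n_genes=100, n_batches=3, n_cell_types=3, seed=7)
    return simulate(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
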