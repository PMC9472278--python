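import numpy as np
import pytest

from rjtrl.fixtures import FixtureSpec, generate_fixtures, mini_vocabulary


@pytest.fixture(scope="session")
def vocab():
    return mini_vocabulary()


@pytest.fixture(scope="session")
def fixture_smiles():
    """A reproducible set of in-vocabulary drug-like molecules."""
    return generate_fixtures(FixtureSpec(seed=7, n_molecules=100, max_nodes=6))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
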