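import numpy as np
import pytest

from thermoscale import GenerativeParams, default_sites, generate_records


@pytest.fixture(scope="session")
def sites():
    return default_sites()


@pytest.fixture(scope="session")
def default_params():
    return GenerativeParams()


@pytest.fixture(scope="session")
def records_default(default_params, sites):
    """One full 375-individual synthetic dataset at the default conditions."""
    return generate_records(default_params, sites, seed=42, levels="all")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
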