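import pytest

from cyp2d6cea import base_case, run_model
from cyp2d6cea.sensitivity import run_psa


@pytest.fixture(scope="session")
def params():
    return base_case()


@pytest.fixture(scope="session")
def base_result(params):
    return run_model(params)


@pytest.fixture(scope="session")
def psa_draws_small(params):
    """A modest PSA sample shared by the sensitivity unit tests."""
    return run_psa(params, n_draws=400, seed=1234)
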