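import pytest
from hypothesis import settings

from embocea.parameters import load_parameters

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def params_itt():
    return load_parameters()


@pytest.fixture(scope="session")
def params_pp(params_itt):
    return params_itt.replace(population="pp", median_pfs_tare=12.83)
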