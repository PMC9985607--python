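import numpy as np
import pytest

from autocyclase import RateParams, build_network


@pytest.fixture(scope="session")
def study_params() -> RateParams:
    """Lumped constants measured for the MSP11 autocyclase system."""
    return RateParams(mode="lumped", k_uni=0.01, k_bi=130.0, k_hyd=0.0)


@pytest.fixture(scope="session")
def study_network(study_params):
    return build_network(4, study_params, "drop")


@pytest.fixture()
def rng():
    return np.random.default_rng(20230304)
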