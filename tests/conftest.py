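import pytest

from rootzn import SimConfig, generate_density, generate_field, generate_solution
from rootzn.reference import group_curves


@pytest.fixture(scope="session")
def tol_curve():
    return group_curves("tolerant")


@pytest.fixture(scope="session")
def sens_curve():
    return group_curves("sensitive")


@pytest.fixture(scope="session")
def noiseless_cfg():
    return SimConfig(seed=1, noise_cv=0.0)


@pytest.fixture(scope="session")
def noiseless_field(noiseless_cfg):
    return generate_field(noiseless_cfg)


@pytest.fixture(scope="session")
def noiseless_density(noiseless_cfg):
    return generate_density(noiseless_cfg)


@pytest.fixture(scope="session")
def noiseless_solution(noiseless_cfg):
    return generate_solution(noiseless_cfg)


@pytest.fixture(scope="session")
def noisy_field():
    return generate_field(SimConfig(seed=7, noise_cv=0.10))
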