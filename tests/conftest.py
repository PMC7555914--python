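import pytest

from damu import LossSpec, PopulationPair, TestModel, case_study


@pytest.fixture(scope="session")
def cfg():
    """Bundled glucose/OGTT case-study configuration."""
    return case_study()


@pytest.fixture(scope="session")
def test1(cfg):
    """Low-uncertainty test (u = 0.023)."""
    return cfg.test1


@pytest.fixture(scope="session")
def test2(cfg):
    """High-uncertainty test (u = 0.23)."""
    return cfg.test2


@pytest.fixture
def equal_pops():
    """Degenerate model: identical populations, so the test is uninformative."""
    return TestModel(PopulationPair(mu_d=1.0, sigma_d=0.8, mu_nd=1.0,
                                    sigma_nd=0.8, v=0.3), u=0.1)


@pytest.fixture(scope="session")
def loss(cfg):
    return cfg.loss


@pytest.fixture
def unit_loss():
    return LossSpec(0.0, 0.0, 1.0, 0.0, 1.0)
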