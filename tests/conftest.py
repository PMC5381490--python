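import pytest
from hypothesis import settings

from tsmirnet.synthetic_data import (
    FixtureConfig,
    generate_expression_fixture,
    generate_genome_fixture,
    generate_target_fixture,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config() -> FixtureConfig:
    return FixtureConfig(seed=11)


@pytest.fixture(scope="session")
def genome_fixture(config):
    return generate_genome_fixture(config)


@pytest.fixture(scope="session")
def expression_fixture(config):
    return generate_expression_fixture(config)


@pytest.fixture(scope="session")
def target_fixture(config):
    return generate_target_fixture(config)
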