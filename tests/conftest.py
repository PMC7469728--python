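import pytest

from riskmeta import ModelConfig, filter_eligible, impute_studies
from riskmeta.synthetic_data import default_spec, generate_studies


@pytest.fixture(scope="session")
def spec():
    return default_spec(seed=1)


@pytest.fixture(scope="session")
def generated(spec):
    """(studies, prevalence table, truth) from the default generator."""
    return generate_studies(spec)


@pytest.fixture(scope="session")
def imputed_studies(generated):
    studies, _, _ = generated
    return impute_studies(filter_eligible(studies).studies)


@pytest.fixture(scope="session")
def prevalences(generated):
    return generated[1]


@pytest.fixture()
def config():
    return ModelConfig(seed=7, n_reps=500)
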