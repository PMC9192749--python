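import pytest

from cropalloc import GeneratorConfig, compute_water_yield, generate_instance


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(n_districts=12, n_years=8, n_states=4, random_seed=11)


@pytest.fixture(scope="session")
def small_instance(small_config):
    return generate_instance(small_config)


@pytest.fixture(scope="session")
def small_water_yield(small_instance):
    return compute_water_yield(small_instance.climate, small_instance.crops)
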