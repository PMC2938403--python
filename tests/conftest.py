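import pytest

from mdpp_cea import (
    ModelConfig,
    MortalityModel,
    default_life_table,
    default_parameter_set,
)


@pytest.fixture(scope="session")
def params():
    return default_parameter_set()


@pytest.fixture(scope="session")
def config():
    return ModelConfig()


@pytest.fixture(scope="session")
def life_table():
    return default_life_table()


@pytest.fixture(scope="session")
def mortality(life_table, params):
    return MortalityModel(life_table=life_table, fraction_female=params.fraction_female.base)
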