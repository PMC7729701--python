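import pytest

from ieev_cea import CostEffectivenessModel, build_life_table, default_parameters


@pytest.fixture(scope="session")
def base_params():
    return default_parameters()


@pytest.fixture(scope="session")
def life_table():
    """Packaged Gompertz stand-in: expectancy 81.0 at birth, slope 0.085."""
    return build_life_table(81.0, 0.085)


@pytest.fixture(scope="session")
def model(base_params, life_table):
    return CostEffectivenessModel(base_params, life_table, age_at_admission=62.0)
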