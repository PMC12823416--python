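import numpy as np
import pytest

from macroburden import ScenarioConfig, SynthConfig, generate_country, toy_country


@pytest.fixture(scope="session")
def toy():
    return toy_country()


@pytest.fixture(scope="session")
def synth_small():
    """Mid-sized synthetic country: enough age structure for every channel,
    small enough for oracle loops."""
    cfg = SynthConfig(n_ages=71, years=(2020, 2040), pop0=1_000_000,
                      gdp0=20_000.0, seed=7, name="small")
    return generate_country(cfg)


@pytest.fixture(scope="session")
def synth_full():
    """Full-resolution synthetic country (101 ages, 31 years)."""
    return generate_country(SynthConfig(seed=11, name="full"))


@pytest.fixture()
def base_cfg():
    return ScenarioConfig()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
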