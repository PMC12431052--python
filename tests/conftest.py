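import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fallstream.synthetic import GeneratorConfig, generate_cohort, generate_trial
from fallstream.transformer import TransformerConfig

settings.register_profile(
    "fallstream",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fallstream")


@pytest.fixture(scope="session")
def gen_config() -> GeneratorConfig:
    return GeneratorConfig(seed=7)


@pytest.fixture(scope="session")
def exact_config() -> GeneratorConfig:
    """Jitter-free generator for tests that need exact time grids."""
    return GeneratorConfig(seed=7, timestamp_jitter_ms=0.0)


@pytest.fixture(scope="session")
def fall_trial(gen_config):
    return generate_trial("right", "S01", gen_config)


@pytest.fixture(scope="session")
def adl_trial(gen_config):
    return generate_trial("wash_hands", "S01", gen_config)


@pytest.fixture(scope="session")
def tiny_cohort(gen_config):
    """Two subjects, one repetition: 10 fall + 16 ADL trials."""
    return generate_cohort(2, 1, gen_config)


@pytest.fixture(scope="session")
def tiny_model_config() -> TransformerConfig:
    """Small architecture for fast unit-test training."""
    return TransformerConfig(n_layers=1, n_heads=2, d_model=16, dropout=0.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
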