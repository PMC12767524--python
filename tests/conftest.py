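import pytest

from nexuskit.synthetic import (
    SyntheticConfig,
    generate_promoter_sequences,
)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Small but fully featured generator configuration."""
    return SyntheticConfig(n_promoters_per_class=10, seed=11)


@pytest.fixture(scope="session")
def small_promoters(small_config):
    """Scrubbed promoter sequences + planted truth, shared across tests."""
    sequences, truths = generate_promoter_sequences(small_config, scrubbed=True)
    return sequences, truths


@pytest.fixture(scope="session")
def clean_config() -> SyntheticConfig:
    """Noise-free configuration: unit expression, no measurement noise."""
    return SyntheticConfig(
        n_promoters_per_class=5,
        seed=5,
        expression_log_sd=0.0,
        occupancy_noise_sd=0.0,
        background_rate=0.0,
    )


@pytest.fixture(scope="session")
def clean_promoters(clean_config):
    return generate_promoter_sequences(clean_config, scrubbed=True)
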