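import pytest

from surnamekit import BuildConfig, WorldConfig, generate_world


@pytest.fixture(scope="session")
def noise_free_world():
    """Synthetic world with no truncation, variants, or missing birthplace."""
    return generate_world(
        WorldConfig(
            seed=7,
            p_variant_spelling=0.0,
            p_truncated_in_reference=0.0,
            p_target_birthplace_missing=0.0,
        )
    )


@pytest.fixture(scope="session")
def default_world():
    """Synthetic world under the default noise conditions."""
    return generate_world(WorldConfig(seed=7))


@pytest.fixture(scope="session")
def build_config():
    return BuildConfig()
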