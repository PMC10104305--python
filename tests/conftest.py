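import pytest

from raphia_allometry import SimConfig, load_published_models, simulate_palm_dataset


@pytest.fixture(scope="session")
def published_models():
    return load_published_models()


@pytest.fixture(scope="session")
def model_by_id(published_models):
    return {m.model_id: m for m in published_models}


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic destructive sample (90 palms, fixed seed)."""
    return simulate_palm_dataset(SimConfig(seed=42))


@pytest.fixture(scope="session")
def palms(default_dataset):
    return default_dataset[0]
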