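import numpy as np
import pytest

from sonotear import PhantomConfig, extract_features, generate_dataset


@pytest.fixture(scope="session")
def default_phantom():
    """The reference phantom study: default config, 50 cases per class."""
    cfg = PhantomConfig(seed=1)
    records, manifest = generate_dataset(cfg)
    return cfg, records, manifest


@pytest.fixture(scope="session")
def phantom_features(default_phantom):
    _, records, _ = default_phantom
    return extract_features(records)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
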