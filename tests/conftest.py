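import pytest

from thalcea import ModelConfig, default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def point(registry):
    return registry.point_estimate()


@pytest.fixture()
def base_config():
    return ModelConfig(start_age=1)
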