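import pytest

from warburgsim import (
    build_default_network,
    default_parameters,
    default_initial_state,
    integrate_to_steady_state,
)


@pytest.fixture(scope="session")
def model():
    return build_default_network()


@pytest.fixture()
def params():
    return default_parameters()


@pytest.fixture()
def init_state():
    return default_initial_state()


@pytest.fixture(scope="session")
def default_result(model):
    """The reference steady state in the default environment (solved once)."""
    return integrate_to_steady_state(model, default_parameters())


@pytest.fixture(scope="session")
def preset_cache():
    """Each scenario preset is executed at most once per test session."""
    from warburgsim.scenarios import run_preset

    cache = {}

    def get(name):
        if name not in cache:
            cache[name] = run_preset(name)
        return cache[name]

    return get
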