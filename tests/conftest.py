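import pytest
from hypothesis import HealthCheck, settings

import cuticle_uptake as cu
from cuticle_uptake.params import NumericsConfig

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def preset():
    """Bundled tomato-cuticle preset at the default 10 g/L drop."""
    return cu.kraemer_preset()


@pytest.fixture(scope="session")
def consts(preset):
    return cu.derive_constants(preset)


@pytest.fixture(scope="session")
def preset_run(preset):
    """One full 48-h simulation of the preset, shared across tests."""
    return cu.simulate(preset, NumericsConfig())


@pytest.fixture()
def coarse_numerics():
    """Cheap settings for tests that only need qualitative behaviour."""
    return NumericsConfig(n_nodes=51, rel_tol=1e-7, abs_tol=1e-9, n_output=200)
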