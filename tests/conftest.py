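import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def default_layout():
    """Default 4 Mb layout at the reference rescaling (lambda=1000)."""
    from tepop.genome_model import rescale_parameters, scenario_preset, build_layout

    params = rescale_parameters(scenario_preset("fig9A"), 1000.0)
    return build_layout(params, np.random.default_rng(1))
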