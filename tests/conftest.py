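import numpy as np
import pytest

from pneumyo.synth import default_profiles, generate_session


@pytest.fixture(scope="session")
def small_session():
    """Six-mode labeled session, 20 s per mode (desk scale)."""
    profiles = default_profiles()
    modes = sorted(profiles)
    return generate_session([profiles[m] for m in modes], [20.0] * len(modes),
                            seed=123)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
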