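import numpy as np
import pytest

from fcnlm import NLMConfig, SpeckleParams, add_speckle, default_phantom_spec, make_phantom


@pytest.fixture(scope="session")
def small_config() -> NLMConfig:
    """A small search/patch geometry that keeps per-test filtering cheap."""
    return NLMConfig(search_radius=4, patch_radius=2)


@pytest.fixture(scope="session")
def small_phantom() -> tuple[np.ndarray, np.ndarray]:
    """64x64 clean/noisy pair with 4-look speckle, fixed seed."""
    clean = make_phantom(default_phantom_spec(64, 64, seed=7))
    noisy = add_speckle(clean, SpeckleParams(looks=4.0, seed=7))
    return clean, noisy
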