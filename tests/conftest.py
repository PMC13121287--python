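import numpy as np
import pytest
from hypothesis import settings

from cacvit.phantom import PhantomConfig, generate_patient

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def desk_config() -> PhantomConfig:
    return PhantomConfig(image_size=64)


@pytest.fixture(scope="session")
def phantom_case(desk_config):
    """One deterministic phantom patient with lesions."""
    # seed chosen so the patient has at least one positive slice
    for seed in range(20):
        case = generate_patient(desk_config, seed=seed)
        if case.truth_lesions:
            return case
    raise RuntimeError("no lesioned phantom found in 20 seeds")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
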