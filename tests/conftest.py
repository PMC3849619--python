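import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

from gabormp import DictionaryConfig, build_dictionary  # noqa: E402


@pytest.fixture(scope="session")
def dict_small():
    """Moderate-density Gabor dictionary on a short epoch."""
    return build_dictionary(DictionaryConfig(epsilon=0.2, n_samples=256))


@pytest.fixture(scope="session")
def dict_allfam():
    """All four atom families on a very short epoch."""
    return build_dictionary(
        DictionaryConfig(
            epsilon=0.3,
            n_samples=128,
            include_families=("gabor", "harmonic", "delta", "gaussian"),
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
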