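import numpy as np
import pytest

from todyn.calibrate import build_to_surrogate
from todyn.wigner import normal_modes, sample_wigner


@pytest.fixture(scope="session")
def model():
    """The calibrated 2-thiooxazole surrogate (built once per session)."""
    return build_to_surrogate()


@pytest.fixture(scope="session")
def modes(model):
    return normal_modes(model)


@pytest.fixture(scope="session")
def wigner_500(modes):
    """The standard 500-sample Wigner ensemble used for spectra/selection."""
    return sample_wigner(modes, n_samples=500, seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
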