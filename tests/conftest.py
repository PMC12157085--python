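import numpy as np
import pytest

from wtanet import WeightSpec, preset_unstructured


@pytest.fixture(scope="session")
def unstructured5() -> WeightSpec:
    return preset_unstructured(5)


@pytest.fixture(scope="session")
def diag_variance_family():
    """mu_J = 0, sigma_J^2 concentrated on the diagonal (value 169)."""

    def family(D: int) -> WeightSpec:
        return WeightSpec(np.zeros((D, D)), np.eye(D) * 169.0)

    return family


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
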