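import numpy as np
import pytest

from plastidyn import ModelParams, calibrate_mI


@pytest.fixture(scope="session")
def default_params() -> ModelParams:
    """Reference configuration: N=3, r=(1, 0.6, 0.2), K=1, c=1, lambda=0, mD=1."""
    return ModelParams()


@pytest.fixture(scope="session")
def calibrated_mI(default_params) -> float:
    """mI matched to the growth-dependent endpoint over the standard duration."""
    return calibrate_mI(default_params)


@pytest.fixture(scope="session")
def calibrated_params(default_params, calibrated_mI) -> ModelParams:
    return default_params.replace(mI=calibrated_mI)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20231006)
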